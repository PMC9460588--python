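"""Rank-test battery, Bonferroni control and compact letter display."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from chiasmap import (
    PairwiseResult,
    bonferroni,
    bonferroni_alpha,
    cis_adjusted_test,
    dunn_pairwise,
    kruskal_wallis,
    letter_groups,
    mann_whitney,
    normality_test,
)
from chiasmap.simulate import MeiosisModel, simulate_cells
from chiasmap.scoring import score_chiasmata


# ---------------------------------------------------------------------------
# Shapiro-Wilk


class TestNormality:
    def test_discrete_chiasma_counts_fail_normality(self):
        model = MeiosisModel(n_pairs=21, lambda_extra=3.0, p_obligate_fail=0.01)
        cells = simulate_cells(model, n_cells=50, seed=5)
        scores = [score_chiasmata(c) for c in cells]
        res = normality_test(scores)
        assert res.p < 0.05

    def test_small_symmetric_sample(self):
        res = normality_test([1.0, 2.0, 3.0])
        assert res.W > 0.95

    def test_constant_sample_degenerate(self):
        res = normality_test([4.0, 4.0, 4.0, 4.0])
        assert res.degenerate
        assert math.isnan(res.p)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            normality_test([1.0, 2.0])


# ---------------------------------------------------------------------------
# Kruskal-Wallis


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis([[3, 3, 3], [3, 3, 3]])
        assert h == 0.0 and p == 1.0

    def test_hand_rank_oracle(self):
        # ranks 1..6, no ties: H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2
        groups = [[1, 2, 3], [4, 5, 6]]
        rbar = 3.5
        h_expected = 12.0 / (6 * 7) * (3 * (2 - rbar) ** 2 + 3 * (5 - rbar) ** 2)
        h, p = kruskal_wallis(groups)
        assert h == pytest.approx(h_expected)
        assert p == pytest.approx(sps.chi2.sf(h_expected, df=1))

    def test_separated_lines_detected(self):
        # distinct per-line effects in the generator are detected reliably
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            groups = []
            for tf in (1.0, 0.95, 0.9):
                model = MeiosisModel(n_pairs=21, lambda_extra=3.0,
                                     p_obligate_fail=0.01, trans_factor=tf)
                cells = simulate_cells(model, n_cells=25, rng=rng)
                groups.append([score_chiasmata(c) for c in cells])
            _, p = kruskal_wallis(groups)
            hits += p < 0.05
        assert hits >= 0.95 * n_rep

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


# ---------------------------------------------------------------------------
# Mann-Whitney


def permutation_mw_pvalue(a, b):
    """Exhaustive two-sided Mann-Whitney p over all group assignments."""
    pooled = np.asarray(list(a) + list(b), dtype=float)
    na = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    us = [
        ranks[list(idx)].sum() - na * (na + 1) / 2
        for idx in itertools.combinations(range(len(pooled)), na)
    ]
    us = np.array(us)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_identical_multisets(self):
        _, p = mann_whitney([1, 2, 2, 3], [1, 2, 2, 3])
        assert p > 0.9

    def test_tiny_exact_enumeration(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_large_shift(self):
        rng = np.random.default_rng(3)
        b = rng.normal(size=50)
        a = b + 10
        _, p = mann_whitney(a, b)
        assert p < 1e-10

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_permutation_oracle_small_n(self, seed):
        # heavy integer ties, total n <= 10
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(2, 6, size=2)
        a = rng.integers(0, 4, size=na).tolist()
        b = rng.integers(0, 4, size=nb).tolist()
        if len(set(a)) == len(a) and len(set(a + b)) == len(a) + len(b):
            b[0] = a[0]  # force at least one tie
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(permutation_mw_pvalue(a, b), abs=1e-12)

    def test_one_sided_alternatives(self):
        _, p_less = mann_whitney([1, 2], [3, 4], alternative="less")
        _, p_greater = mann_whitney([1, 2], [3, 4], alternative="greater")
        assert p_less == pytest.approx(1 / 6)
        assert p_greater == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Dunn all-pairs


class TestDunn:
    def test_identical_groups_nothing_significant(self):
        groups = {"a": [1, 2, 3, 4], "b": [1, 2, 3, 4], "c": [1, 2, 3, 4]}
        results = dunn_pairwise(groups, alpha=0.05)
        assert len(results) == 3
        assert not any(r.significant for r in results)

    def test_separated_groups_all_significant(self):
        # fully separated ranks, groups large enough for the z-test to
        # resolve adjacent groups after Bonferroni adjustment
        groups = {
            "a": list(range(1, 16)),
            "b": list(range(16, 31)),
            "c": list(range(31, 46)),
        }
        results = dunn_pairwise(groups, alpha=0.05)
        assert all(r.significant for r in results)

    def test_adjusted_never_below_raw(self):
        groups = {"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5], "d": [1, 5, 9]}
        for r in dunn_pairwise(groups):
            assert r.p_adjusted >= r.p_raw

    def test_agrees_with_label_permutation(self):
        # z-test p close to the exhaustive label-permutation p, small groups
        groups = {"a": [1.0, 5.0, 9.0], "b": [2.0, 6.0, 10.0],
                  "c": [12.0, 15.0, 18.0]}
        results = dunn_pairwise(groups, adjust="none")
        pooled = np.array(sum((groups[k] for k in groups), []))
        ranks = sps.rankdata(pooled)
        idx_all = set(range(9))
        # null distribution of |mean-rank difference| between two groups of 3
        diffs = []
        for ia in itertools.combinations(range(9), 3):
            for ib in itertools.combinations(sorted(idx_all - set(ia)), 3):
                diffs.append(abs(np.mean(ranks[list(ia)]) - np.mean(ranks[list(ib)])))
        diffs = np.array(diffs)
        obs = {"a": ranks[0:3], "b": ranks[3:6], "c": ranks[6:9]}
        for r in results:
            d_obs = abs(np.mean(obs[r.line_a]) - np.mean(obs[r.line_b]))
            p_perm = float(np.mean(diffs >= d_obs - 1e-9))
            assert abs(r.p_raw - p_perm) < 0.12

    def test_needs_three_groups(self):
        with pytest.raises(ValueError):
            dunn_pairwise({"a": [1], "b": [2]})


# ---------------------------------------------------------------------------
# Bonferroni


class TestBonferroni:
    def test_altered_alpha_family_of_27(self):
        assert round(bonferroni_alpha(0.05, 27), 5) == 0.00185

    def test_identity_and_cap(self):
        assert bonferroni([0.03], m=1) == [0.03]
        assert bonferroni([0.4], m=4) == [1.0]

    def test_monotone_in_family_size(self):
        p = [0.001, 0.02, 0.3]
        prev = bonferroni(p, m=1)
        for m in range(2, 30):
            cur = bonferroni(p, m=m)
            assert all(c >= pr for c, pr in zip(cur, prev))
            prev = cur

    def test_invalid_family(self):
        with pytest.raises(ValueError):
            bonferroni([0.1], m=0)


# ---------------------------------------------------------------------------
# Compact letter display


def make_pairwise(sig_pairs, lines, trait="chiasmata"):
    """Build a complete pairwise matrix with given significant pairs."""
    out = []
    for a, b in itertools.combinations(lines, 2):
        s = frozenset((a, b)) in sig_pairs
        p = 0.001 if s else 0.5
        out.append(PairwiseResult(line_a=a, line_b=b, trait=trait,
                                  statistic=0.0, p_raw=p, p_adjusted=p,
                                  significant=s))
    return out


class TestLetterGroups:
    def test_all_non_significant_single_letter(self):
        lines = ["w", "x", "y"]
        means = {"w": 3.0, "x": 2.0, "y": 1.0}
        res = letter_groups(make_pairwise(set(), lines), means)
        assert res.representable
        assert set(res.letters.values()) == {"A"}

    def test_all_significant_distinct_letters(self):
        lines = ["w", "x", "y"]
        sig = {frozenset(p) for p in itertools.combinations(lines, 2)}
        means = {"w": 3.0, "x": 2.0, "y": 1.0}
        res = letter_groups(make_pairwise(sig, lines), means)
        assert res.representable
        assert res.letters == {"w": "A", "x": "B", "y": "C"}

    def test_overlapping_chain(self):
        # w~x, x~y significant-free, w vs y significant: letters A,AB/B pattern
        lines = ["w", "x", "y"]
        sig = {frozenset(("w", "y"))}
        means = {"w": 3.0, "x": 2.0, "y": 1.0}
        res = letter_groups(make_pairwise(sig, lines), means)
        assert res.representable
        assert res.letters["w"] != res.letters["y"]
        assert set(res.letters["x"].split(",")) == (
            set(res.letters["w"].split(",")) | set(res.letters["y"].split(","))
        )

    def test_non_contiguous_relation_flagged_na(self):
        # means 3 > 2 > 1; extremes equivalent but middle differs from both
        lines = ["w", "x", "y"]
        sig = {frozenset(("w", "x")), frozenset(("x", "y"))}
        means = {"w": 3.0, "x": 2.0, "y": 1.0}
        res = letter_groups(make_pairwise(sig, lines), means)
        assert not res.representable
        assert None in res.letters.values()

    def test_incomplete_matrix_rejected(self):
        lines = ["w", "x", "y"]
        pw = make_pairwise(set(), lines)[:-1]
        with pytest.raises(ValueError):
            letter_groups(pw, {"w": 3.0, "x": 2.0, "y": 1.0})

    @pytest.mark.parametrize("seed", range(30))
    def test_share_letter_iff_non_significant(self, seed):
        # brute force over random relations, up to 8 groups
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 9))
        lines = [f"g{i}" for i in range(k)]
        means = {l: float(k - i) for i, l in enumerate(lines)}
        sig = {
            frozenset(p)
            for p in itertools.combinations(lines, 2)
            if rng.random() < 0.4
        }
        res = letter_groups(make_pairwise(sig, lines), means)
        if not res.representable:
            return  # NA outcome checked elsewhere
        for a, b in itertools.combinations(lines, 2):
            share = bool(set(res.letters[a].split(",")) &
                         set(res.letters[b].split(",")))
            assert share == (frozenset((a, b)) not in sig), (a, b, res.letters)


# ---------------------------------------------------------------------------
# cis-adjusted contrast


class TestCisAdjusted:
    def test_zero_delta_matches_unadjusted(self):
        rng = np.random.default_rng(2)
        a = rng.normal(40, 1, 30).tolist()
        b = rng.normal(39, 1, 30).tolist()
        res = cis_adjusted_test(a, b, delta=0.0)
        _, p = mann_whitney(a, b)
        assert res.p_raw == pytest.approx(p)

    def test_exact_shift_not_significant(self):
        rng = np.random.default_rng(4)
        b = rng.normal(39.0, 1.0, 50).tolist()
        a = [x + 1.0 for x in b]
        res = cis_adjusted_test(a, b, delta=1.0)
        assert not res.significant

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            cis_adjusted_test([1.0], [1.0], delta=-1.0)
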