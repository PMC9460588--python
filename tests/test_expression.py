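"""Triad expression rules, bin summaries, hit filtering and triage."""

import numpy as np
import pandas as pd
import pytest

from chiasmap import (
    AlignmentHit,
    ExpressionTriad,
    bin_expression_summary,
    filter_hits,
    functionality_triage,
    is_expressed,
    overexpressed_on_B,
    reference,
    triad_max,
)
from chiasmap.expression import read_fpkm_table


def triad(a=None, b=None, d=None):
    fpkm = {}
    for copy, v in (("A", a), ("B", b), ("D", d)):
        if v is not None:
            fpkm[copy] = np.atleast_2d(np.asarray(v, dtype=float))
    return ExpressionTriad(gene_id_b="g", fpkm=fpkm)


class TestIsExpressed:
    def test_all_below_threshold(self):
        assert not is_expressed([[4.9], [4.9], [4.9], [4.9]])

    def test_threshold_is_strict(self):
        assert not is_expressed([[5.0], [0.0]])

    def test_one_condition_above(self):
        assert is_expressed([[5.1], [0.0], [0.0], [0.0]])

    def test_replicates_averaged_before_comparison(self):
        # single stage, replicates 9 and 2: stage mean 5.5 > 5
        assert is_expressed([[9.0, 2.0]])
        # stage mean 4.5 even though one replicate exceeds 5
        assert not is_expressed([[7.0, 2.0]])

    def test_no_values_rejected(self):
        with pytest.raises(ValueError):
            is_expressed(np.empty((0, 0)))


class TestOverexpressedOnB:
    def test_clear_overexpression(self):
        assert overexpressed_on_B(triad(a=[[4.0]], b=[[10.0]], d=[[4.0]]))

    def test_fold_change_must_exceed_both(self):
        assert not overexpressed_on_B(triad(a=[[6.0]], b=[[10.0]], d=[[4.0]]))

    def test_fold_threshold_strict(self):
        assert not overexpressed_on_B(triad(a=[[5.0]], b=[[10.0]], d=[[5.0]]))

    def test_missing_homoeologues_count_as_overexpressed(self):
        assert overexpressed_on_B(triad(b=[[1.0]]))
        assert overexpressed_on_B(triad(a=[[0.4]], b=[[1.0]]))

    def test_zero_homoeologue_with_expressed_b(self):
        assert overexpressed_on_B(triad(a=[[0.0]], b=[[3.0]], d=[[0.0]]))

    def test_b_absent_rejected(self):
        with pytest.raises(ValueError):
            overexpressed_on_B(triad(a=[[1.0]], d=[[1.0]]))

    def test_scale_invariance(self):
        t1 = triad(a=[[4.0, 6.0]], b=[[30.0, 10.0]], d=[[2.0, 5.0]])
        for k in (0.01, 1.0, 250.0):
            t2 = triad(a=[[4.0 * k, 6.0 * k]], b=[[30.0 * k, 10.0 * k]],
                       d=[[2.0 * k, 5.0 * k]])
            assert overexpressed_on_B(t2) == overexpressed_on_B(t1)
            assert triad_max(t2) == triad_max(t1)


class TestTriadMax:
    @pytest.mark.parametrize(
        "gene", [g for g, c in reference.MOST_EXPRESSED_COPY.items()
                 if c is not None])
    def test_matches_published_most_expressed_copy(self, gene):
        row = reference.meiotic_gene_table().set_index("gene").loc[gene]
        fpkm = {c: [[v]] for c, v in (("A", row.fpkm_a), ("B", row.fpkm_b),
                                      ("D", row.fpkm_d)) if pd.notna(v)}
        t = ExpressionTriad(gene_id_b=str(row.gene_id_b), fpkm=fpkm)
        assert triad_max(t) == reference.MOST_EXPRESSED_COPY[gene]

    def test_tie_reported(self):
        assert triad_max(triad(a=[[2.0]], b=[[2.0]], d=[[1.0]])) == "tie"

    def test_single_copy_rejected(self):
        with pytest.raises(ValueError):
            triad_max(triad(b=[[2.0]]))


def table2_fixture():
    rows = []
    for r in reference.bin_summary_table().itertuples():
        for i in range(r.n_mapped):
            rows.append({
                "gene": f"{r.bin}:{i}", "bin": r.bin, "arm": r.arm,
                "expressed": i < r.n_expressed,
                "overexpressed_b": i < r.n_overexpressed_b,
            })
    return pd.DataFrame(rows)


class TestBinSummary:
    def test_published_percentages(self):
        out = bin_expression_summary(table2_fixture()).set_index("bin")
        ref = reference.bin_summary_table().set_index("bin")
        for b in ref.index:
            assert out.loc[b, "pct_expressed"] == ref.loc[b, "pct_expressed"]
        assert out.loc["Total Assigned", "n_mapped"] == 6060
        assert out.loc["Total Assigned", "n_expressed"] == 2099
        assert out.loc["Total Assigned", "pct_expressed"] == 34.64

    def test_counts_conserved_across_totals(self):
        out = bin_expression_summary(table2_fixture()).set_index("bin")
        bins = out[~out.index.str.startswith("Total")]
        for col in ("n_mapped", "n_expressed", "n_overexpressed_b"):
            assert bins[col].sum() == out.loc["Total Assigned", col]
            assert (bins.groupby(bins["arm"])[col].sum().sum()
                    == out.loc["Total Assigned", col])

    def test_empty_bin_flagged(self):
        genes = pd.DataFrame([
            {"gene": "g1", "bin": "b1", "arm": "S", "expressed": True},
        ])
        from chiasmap import DeletionBin
        bins = [DeletionBin(name="b1", arm="S", fl_low=0.0, fl_high=0.5),
                DeletionBin(name="b2", arm="S", fl_low=0.5, fl_high=1.0)]
        out = bin_expression_summary(genes, bins).set_index("bin")
        assert out.loc["b2", "n_mapped"] == 0
        assert out.loc["b2", "pct_expressed"] == 0.0
        assert bool(out.loc["b2", "empty"])

    def test_gene_without_bin_rejected(self):
        genes = pd.DataFrame([
            {"gene": "g1", "bin": None, "arm": "S", "expressed": True},
        ])
        with pytest.raises(ValueError, match="without a bin"):
            bin_expression_summary(genes)


def hit(score, ident, sim, q="q", t="t"):
    return AlignmentHit(query=q, target_gene=t, score=score,
                        identity_pct=ident, similarity_pct=sim)


class TestFilterHits:
    def test_passing_hit_kept(self):
        assert filter_hits([hit(600, 45, 65)]) == [hit(600, 45, 65)]

    @pytest.mark.parametrize("h", [
        hit(500, 80, 90),   # score at the cut-off: strict, dropped
        hit(600, 40, 90),
        hit(600, 55, 60),
    ])
    def test_cutoffs_strict(self, h):
        assert filter_hits([h]) == []

    def test_toy_table_order_stable(self):
        hits = [
            hit(600, 45, 65, q="q1"), hit(499, 45, 65, q="q2"),
            hit(700, 39, 80, q="q3"), hit(801, 41, 61, q="q4"),
            hit(900, 90, 95, q="q5"), hit(100, 10, 20, q="q6"),
            hit(501, 40.5, 60.5, q="q7"), hit(500, 41, 61, q="q8"),
            hit(2000, 45, 59, q="q9"), hit(1000, 70, 85, q="q10"),
        ]
        kept = filter_hits(hits)
        assert [h.query for h in kept] == ["q1", "q4", "q5", "q7", "q10"][:len(kept)]
        assert [h.query for h in kept] == ["q1", "q4", "q5", "q7", "q10"]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        hits = [hit(float(s), float(i), float(min(100, i + 20)))
                for s, i in zip(rng.uniform(0, 1500, 50),
                                rng.uniform(0, 80, 50))]
        base = set(h.query + str(h.score) for h in filter_hits(hits))
        for kwargs in ({"score_min": 800}, {"id_min": 60}, {"sim_min": 75}):
            tighter = set(h.query + str(h.score)
                          for h in filter_hits(hits, **kwargs))
            assert tighter <= base


class TestFunctionalityTriage:
    A = "MKLVDEAQRST"
    D = "MKLVDEAQRST"

    def polyploids(self, n=11, a=None, b=None, d=None):
        mk = lambda seq: {f"v{i}": seq for i in range(n)}
        return (mk(a or self.A), mk(b or self.A), mk(d or self.D))

    def test_all_identical_all_functional(self):
        pa, pb, pd_ = self.polyploids()
        calls = functionality_triage("g", self.A, self.D, pa, pb, pd_)
        assert all(c.status == "functional" for c in calls)

    def test_premature_stop_flags_b(self):
        pa, pb, pd_ = self.polyploids(b="MKLV*EAQRST")
        calls = {c.copy: c for c in
                 functionality_triage("g", self.A, self.D, pa, pb, pd_)}
        assert calls["B"].status == "doubtful"
        assert any("premature stop" in e for e in calls["B"].evidence)
        assert calls["A"].status == "functional"

    def test_gap_at_conserved_position_flags(self):
        pa, pb, pd_ = self.polyploids(a="MKLV-EAQRST")
        calls = {c.copy: c for c in
                 functionality_triage("g", self.A, self.D, pa, pb, pd_)}
        assert calls["A"].status == "doubtful"

    def test_recurrent_substitution_flags_a(self):
        # deviation in 9 of 11 varieties at a conserved position
        pa = {f"v{i}": ("MKLVDEAQRSG" if i < 9 else self.A) for i in range(11)}
        _, pb, pd_ = self.polyploids()
        calls = {c.copy: c for c in
                 functionality_triage("g", self.A, self.D, pa, pb, pd_)}
        assert calls["A"].status == "doubtful"
        assert any("9/11" in e for e in calls["A"].evidence)

    def test_rare_substitution_not_flagged(self):
        pa = {f"v{i}": ("MKLVDEAQRSG" if i < 2 else self.A) for i in range(11)}
        _, pb, pd_ = self.polyploids()
        calls = {c.copy: c for c in
                 functionality_triage("g", self.A, self.D, pa, pb, pd_)}
        assert calls["A"].status == "functional"

    def test_diploid_divergent_positions_masked(self):
        # diploids differ at the last position: deviations there are neutral
        d_div = "MKLVDEAQRSX"
        pa = {f"v{i}": "MKLVDEAQRSY" for i in range(11)}
        _, pb, pd_ = self.polyploids(n=11)
        calls = {c.copy: c for c in
                 functionality_triage("g", self.A, d_div, pa, pb, pd_)}
        assert calls["A"].status == "functional"

    def test_unequal_lengths_rejected(self):
        pa, pb, pd_ = self.polyploids()
        with pytest.raises(ValueError, match="length"):
            functionality_triage("g", self.A + "Q", self.D, pa, pb, pd_)


def test_fpkm_table_round_trip(tmp_path, paper_bins):
    from chiasmap import make_gene_fixture

    genes, fpkm, _ = make_gene_fixture(paper_bins[:2], n_genes_per_bin=5, seed=3)
    path = tmp_path / "fpkm.tsv"
    fpkm.to_csv(path, sep="\t", index=False)
    triads = read_fpkm_table(path)
    assert set(triads) == set(genes["gene"])
    some = triads[genes["gene"].iloc[0]]
    assert set(some.fpkm) == {"A", "B", "D"}
    assert some.fpkm["B"].shape == (4, 2)
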