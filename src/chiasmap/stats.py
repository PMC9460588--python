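"""Non-parametric comparison battery for per-cell chiasma counts.

Chiasma counts are small integers with heavy ties, so the battery is
rank-based throughout: Shapiro-Wilk to document non-normality, a global
Kruskal-Wallis test across lines, Mann-Whitney for two-line contrasts
(exact where enumerable, tie-corrected normal approximation otherwise),
Dunn's z-tests on pooled ranks for the all-pairs comparisons behind the
compact letter display, and Bonferroni control of the family-wise error.

The letter display follows the insert-and-absorb convention: lines are
ordered by trait mean and contiguous runs of mutually non-significant
lines share a letter. When non-significance is not contiguous under the
mean ordering (x ~ z but an intermediate y differs from one of them) no
letter assignment can represent the relation; the affected lines are
flagged NA instead of being forced into a misleading grouping.

A cis-adjusted contrast shifts the reference sample down by the chiasma
loss expected from the deleted segment itself (default one chiasma)
before testing, separating segment-local (cis) loss from genome-wide
(trans) effects.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairwiseResult",
    "LetterAssignment",
    "NormalityResult",
    "normality_test",
    "kruskal_wallis",
    "mann_whitney",
    "dunn_pairwise",
    "bonferroni",
    "bonferroni_alpha",
    "letter_groups",
    "cis_adjusted_test",
]


@dataclass(frozen=True)
class PairwiseResult:
    """One two-line comparison for one trait."""

    line_a: str
    line_b: str
    trait: str
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0 and 0.0 <= self.p_adjusted <= 1.0):
            raise ValueError("p-values must lie in [0, 1]")
        if self.p_adjusted + 1e-12 < self.p_raw:
            raise ValueError("adjusted p-value cannot be below the raw one")


@dataclass(frozen=True)
class LetterAssignment:
    """Compact letter display for one trait.

    ``letters`` maps line -> letter string, or ``None`` for lines whose
    grouping is not representable (NA). ``representable`` is True only
    when every line received letters.
    """

    trait: str
    letters: dict[str, str | None]
    representable: bool


@dataclass(frozen=True)
class NormalityResult:
    W: float
    p: float
    degenerate: bool = False


def normality_test(sample: Sequence[float]) -> NormalityResult:
    """Shapiro-Wilk test; a constant sample yields a flagged degenerate result."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if np.ptp(x) == 0:
        return NormalityResult(W=float("nan"), p=float("nan"), degenerate=True)
    w, p = sps.shapiro(x)
    return NormalityResult(W=float(w), p=float(p))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p on k-1 df."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tied groups in the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _exact_u_pvalue(a: np.ndarray, b: np.ndarray, u: float, alternative: str) -> float:
    """Two-sided/one-sided Mann-Whitney p by enumerating group assignments.

    Valid with ties (works on midranks); feasible only for small samples.
    """
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na = len(a)
    offset = na * (na + 1) / 2.0
    us = np.array([
        sum(ranks[list(idx)]) - offset
        for idx in itertools.combinations(range(len(pooled)), na)
    ])
    total = len(us)
    eps = 1e-9
    p_le = np.sum(us <= u + eps) / total
    p_ge = np.sum(us >= u - eps) / total
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(p_le, p_ge))
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    raise ValueError(f"unknown alternative {alternative!r}")


_EXACT_ENUM_LIMIT = 200_000


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney U test with midrank tie handling.

    Small samples are tested exactly — by the standard no-tie recursion,
    or by full enumeration of group assignments when ties are present and
    the assignment count is enumerable. Larger samples use the normal
    approximation with tie-corrected variance and continuity correction.
    Returns ``(U, p)`` with U counted for the first sample.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([xa, xb]))) < xa.size + xb.size
    small = max(xa.size, xb.size) < 20

    ranks = sps.rankdata(np.concatenate([xa, xb]))
    u_a = float(np.sum(ranks[: xa.size]) - xa.size * (xa.size + 1) / 2.0)

    if small and not has_ties:
        res = sps.mannwhitneyu(xa, xb, alternative=alternative, method="exact")
        return float(res.statistic), float(res.pvalue)
    if small and math.comb(xa.size + xb.size, xa.size) <= _EXACT_ENUM_LIMIT:
        return u_a, _exact_u_pvalue(xa, xb, u_a, alternative)
    res = sps.mannwhitneyu(
        xa, xb, alternative=alternative, method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def _adjust(p_raw: list[float], method: str) -> list[float]:
    m = len(p_raw)
    if method == "none" or m == 0:
        return list(p_raw)
    if method == "bonferroni":
        return [min(1.0, m * p) for p in p_raw]
    if method == "holm":
        order = sorted(range(m), key=lambda i: p_raw[i])
        adj = [0.0] * m
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p_raw[i])
            adj[i] = min(1.0, running)
        return adj
    raise ValueError(f"unknown adjustment {method!r}")


def dunn_pairwise(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    trait: str = "trait",
    adjust: str = "bonferroni",
) -> list[PairwiseResult]:
    """Dunn's post-hoc z-tests on pooled ranks, all pairs of groups.

    z for a pair is the mean-rank difference scaled by the tie-corrected
    pooled-rank standard error; p-values are two-sided ("bilateral") and
    adjusted for the k(k-1)/2 comparisons (configurable).
    """
    names = list(groups)
    if len(names) < 3:
        raise ValueError("Dunn's procedure needs at least three groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size == 0 for a in arrays.values()):
        raise ValueError("empty group")
    pooled = np.concatenate([arrays[k] for k in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    sizes: dict[str, int] = {}
    pos = 0
    for k in names:
        n_k = arrays[k].size
        mean_rank[k] = float(np.mean(ranks[pos: pos + n_k]))
        sizes[k] = n_k
        pos += n_k

    tie = _tie_term(pooled)
    var_base = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))

    pairs = list(itertools.combinations(names, 2))
    zs, p_raw = [], []
    for a, b in pairs:
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = 0.0 if se == 0 else (mean_rank[a] - mean_rank[b]) / se
        zs.append(z)
        p_raw.append(min(1.0, 2.0 * float(sps.norm.sf(abs(z)))))
    p_adj = _adjust(p_raw, adjust)
    return [
        PairwiseResult(
            line_a=a, line_b=b, trait=trait, statistic=z,
            p_raw=pr, p_adjusted=pa, significant=pa < alpha,
        )
        for (a, b), z, pr, pa in zip(pairs, zs, p_raw, p_adj)
    ]


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni-adjusted p-values, ``min(1, m p)`` with m defaulting to the family size."""
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return [min(1.0, m * float(p)) for p in p_values]


def bonferroni_alpha(alpha: float, m: int) -> float:
    """The altered per-comparison significance level alpha / m."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# Compact letter display


def _letter(i: int) -> str:
    # A..Z, then AA, AB, ...
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("A") + rem) + out
    return out


def letter_groups(
    pairwise: Sequence[PairwiseResult],
    means: Mapping[str, float],
    trait: str | None = None,
) -> LetterAssignment:
    """Assign compact letters per line from a complete pairwise matrix.

    Lines are ordered by decreasing mean (highest mean gets the earliest
    letter). Contiguous runs of mutually non-significant lines share a
    letter; maximal runs each get one letter and contained runs are
    absorbed. Lines involved in a non-contiguity violation — a
    non-significant pair separated by a line that differs from one of
    them — are flagged NA (letters ``None``).
    """
    lines = sorted(means, key=lambda k: (-means[k], k))
    if trait is None:
        traits = {r.trait for r in pairwise}
        if len(traits) != 1:
            raise ValueError("pairwise results span multiple traits; pass trait=")
        trait = traits.pop()

    sig: dict[frozenset[str], bool] = {}
    for r in pairwise:
        sig[frozenset((r.line_a, r.line_b))] = r.significant
    for a, b in itertools.combinations(lines, 2):
        if frozenset((a, b)) not in sig:
            raise ValueError(f"missing pairwise comparison {a} vs {b}")

    def nonsig(a: str, b: str) -> bool:
        return not sig[frozenset((a, b))]

    # Iteratively remove lines involved in non-contiguity violations.
    active = list(lines)
    flagged: set[str] = set()
    while True:
        violation = None
        for i, j, k in itertools.combinations(range(len(active)), 3):
            x, y, z = active[i], active[j], active[k]
            if nonsig(x, z) and (not nonsig(x, y) or not nonsig(y, z)):
                violation = (x, y, z)
                break
        if violation is None:
            break
        flagged.update(violation)
        active = [l for l in active if l not in flagged]

    # Maximal contiguous non-significant runs over the remaining lines.
    intervals: list[tuple[int, int]] = []
    n = len(active)
    for i in range(n):
        j = i
        while j + 1 < n and all(nonsig(active[t], active[j + 1]) for t in range(i, j + 1)):
            j += 1
        intervals.append((i, j))
    maximal = [
        iv for iv in intervals
        if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in intervals)
    ]
    maximal = sorted(set(maximal))

    letters: dict[str, str | None] = {l: None for l in lines}
    for idx, (lo, hi) in enumerate(maximal):
        lab = _letter(idx)
        for t in range(lo, hi + 1):
            cur = letters[active[t]]
            letters[active[t]] = lab if cur is None else cur + "," + lab
    for l in flagged:
        letters[l] = None
    return LetterAssignment(trait=trait, letters=letters,
                            representable=not flagged)


def cis_adjusted_test(
    reference: Sequence[float],
    deletion_line: Sequence[float],
    delta: float = 1.0,
    test: Callable[..., tuple[float, float]] | None = None,
    alpha: float = 0.05,
    line_a: str = "reference",
    line_b: str = "deletion",
    trait: str = "chiasmata",
) -> PairwiseResult:
    """Two-sample test after removing the expected cis loss from the reference.

    The reference sample is shifted down by ``delta`` chiasmata (the loss
    attributable to the deleted segment itself) before applying the
    two-sample test. A contrast that is significant unadjusted but not
    after the shift is consistent with a purely cis effect.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if test is None:
        test = mann_whitney
    shifted = [x - delta for x in reference]
    stat, p = test(shifted, deletion_line)
    return PairwiseResult(
        line_a=line_a, line_b=line_b, trait=trait, statistic=stat,
        p_raw=p, p_adjusted=p, significant=p < alpha,
    )
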