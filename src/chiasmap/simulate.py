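"""Seedable generator of per-cell metaphase-I configurations.

The generative model is deliberately minimal: each homologous pair forms
its obligate crossover with probability ``trans_factor * (1 -
p_obligate_fail)`` and, when bound, adds ``Poisson(lambda_extra *
trans_factor)`` extra crossovers. A pair with no crossover appears as
two univalents, with exactly one as a rod bivalent, with two or more as
a ring — the trichotomy actually scored on slides (a ring is scored as
two chiasmata regardless of how many crossovers it hides, so scoring
saturates at two per bivalent).

Deletion effects enter two ways. A *trans* (genome-wide) effect scales
both the obligate-success probability and the extra-crossover rate
through ``trans_factor``. A *cis* effect removes the crossovers that
would have formed on the deleted segment of the carrier pair:
``cis_loss`` chiasmata (in expectation) are subtracted from that pair's
score after classification, demoting ring -> rod -> two univalents.
Telosome pairs (one-armed, as in ditelosomic lines) can at best form a
rod. Chromosome-unit accounting holds for every generated cell by
construction.

A companion fixture generator plants gene positions, triad FPKM values
and alignment hits with controlled expressed / B-overexpressed
fractions, so the expression screen is testable without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bins import DeletionBin
from .scoring import PMCConfiguration

__all__ = [
    "MeiosisModel",
    "MomentFit",
    "simulate_cells",
    "fit_moments",
    "model_from_line_means",
    "builtin_scenarios",
    "make_gene_fixture",
]


@dataclass(frozen=True)
class MeiosisModel:
    """Parameters of the per-bivalent crossover model.

    n_pairs: homologous pairs capable of forming rings (21 for euploid).
    n_telosome_pairs: one-armed pairs (rod at best), e.g. 1 for Dt lines.
    lambda_extra: mean extra crossovers per bound pair beyond the
        obligate one (unitless rate; ~3 reproduces euploid ring counts).
    p_obligate_fail: baseline probability a pair forms no crossover.
    trans_factor: genome-wide multiplier in (0, 1]; scales both the
        obligate-success probability and the extra-crossover rate.
    cis_loss: expected chiasmata removed from the deletion-carrier pair
        (segment-local effect); 0 for intact lines.
    quadrivalent_rate: per-(pair-couple) probability that two pairs
        associate into a quadrivalent (scored 4); off by default.
    """

    n_pairs: int = 21
    n_telosome_pairs: int = 0
    lambda_extra: float = 3.0
    p_obligate_fail: float = 0.0
    trans_factor: float = 1.0
    cis_loss: float = 0.0
    quadrivalent_rate: float = 0.0
    line_id: str = "sim"

    def __post_init__(self) -> None:
        if self.n_pairs < 0 or self.n_telosome_pairs < 0:
            raise ValueError("pair counts must be non-negative")
        if self.lambda_extra < 0:
            raise ValueError("lambda_extra must be non-negative")
        if not 0.0 <= self.p_obligate_fail <= 1.0:
            raise ValueError("p_obligate_fail must lie in [0, 1]")
        if not 0.0 < self.trans_factor <= 1.0:
            raise ValueError("trans_factor must lie in (0, 1]")
        if self.cis_loss < 0:
            raise ValueError("cis_loss must be non-negative")
        if not 0.0 <= self.quadrivalent_rate <= 1.0:
            raise ValueError("quadrivalent_rate must lie in [0, 1]")

    @property
    def total_units(self) -> int:
        """Declared 2n in chromosome units (telosomes count one unit each)."""
        return 2 * (self.n_pairs + self.n_telosome_pairs)

    # -- analytic moments ---------------------------------------------------

    @property
    def p_bound(self) -> float:
        """Probability a pair forms at least one crossover."""
        return self.trans_factor * (1.0 - self.p_obligate_fail)

    @property
    def p_ring_given_bound(self) -> float:
        return 1.0 - math.exp(-self.lambda_extra * self.trans_factor)

    def _pair_score_dist(self) -> tuple[float, float, float]:
        """P(score = 0, 1, 2) for a normal non-carrier pair."""
        s = self.p_bound
        p_ring = s * self.p_ring_given_bound
        p_rod = s - p_ring
        return 1.0 - s, p_rod, p_ring

    def expected_chiasmata(self) -> float:
        """Analytic mean chiasma score per cell.

        Exact for quadrivalent_rate = 0; with quadrivalents the carrier
        pair is assumed never to be consumed by one.
        """
        p0, p1, p2 = self._pair_score_dist()
        e_pair = p1 + 2.0 * p2

        c_int = int(math.floor(self.cis_loss))
        c_frac = self.cis_loss - c_int
        e_carrier = 0.0
        for extra, p_extra in ((0, 1.0 - c_frac), (1, c_frac)):
            b = c_int + extra
            e_carrier += p_extra * (
                p1 * max(0, 1 - b) + p2 * max(0, 2 - b)
            )
        has_carrier = self.cis_loss > 0 and self.n_pairs >= 1

        n_couples = self.n_pairs // 2
        e_quads = n_couples * self.quadrivalent_rate
        n_normal = self.n_pairs - 2.0 * e_quads - (1 if has_carrier else 0)
        total = n_normal * e_pair + 4.0 * e_quads
        if has_carrier:
            total += e_carrier
        total += self.n_telosome_pairs * self.p_bound
        return total


def simulate_cells(
    model: MeiosisModel,
    n_cells: int = 50,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[PMCConfiguration]:
    """Draw metaphase-I configurations for ``n_cells`` cells.

    Fully determined by the seed (or generator state); every cell
    satisfies the chromosome-unit accounting for the model's 2n.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    n_pairs = model.n_pairs
    s = model.p_bound
    lam = model.lambda_extra * model.trans_factor

    if n_pairs > 0:
        bound = rng.random((n_cells, n_pairs)) < s
        extras = rng.poisson(lam, size=(n_cells, n_pairs))
        score = np.where(bound, np.where(extras > 0, 2, 1), 0)
    else:
        score = np.zeros((n_cells, 0), dtype=int)

    # cis effect on the carrier pair (column 0)
    if model.cis_loss > 0 and n_pairs >= 1:
        c_int = int(math.floor(model.cis_loss))
        c_frac = model.cis_loss - c_int
        removal = c_int + (rng.random(n_cells) < c_frac).astype(int)
        score[:, 0] = np.maximum(0, score[:, 0] - removal)

    # quadrivalents consume couples of pairs from the distal columns
    n_couples = n_pairs // 2
    if model.quadrivalent_rate > 0 and n_couples > 0:
        n_quad = rng.binomial(n_couples, model.quadrivalent_rate, size=n_cells)
    else:
        n_quad = np.zeros(n_cells, dtype=int)
    cols = np.arange(n_pairs)
    used = cols[None, :] < (n_pairs - 2 * n_quad)[:, None]

    rings = ((score == 2) & used).sum(axis=1)
    rods = ((score == 1) & used).sum(axis=1)
    univ = 2 * ((score == 0) & used).sum(axis=1)

    if model.n_telosome_pairs > 0:
        t_bound = rng.random((n_cells, model.n_telosome_pairs)) < s
        rods = rods + t_bound.sum(axis=1)
        univ = univ + 2 * (~t_bound).sum(axis=1)

    return [
        PMCConfiguration(
            line_id=model.line_id,
            cell_id=f"{model.line_id}_c{i + 1}",
            univalents=int(univ[i]),
            rods=int(rods[i]),
            rings=int(rings[i]),
            quadrivalents=int(n_quad[i]),
        )
        for i in range(n_cells)
    ]


@dataclass(frozen=True)
class MomentFit:
    """Method-of-moments estimates from scored cells (trans_factor = 1 assumed)."""

    model: MeiosisModel
    boundary: bool = False


def fit_moments(cells: Sequence[PMCConfiguration],
                n_pairs: int | None = None) -> MomentFit:
    """Estimate p_obligate_fail and lambda_extra from configuration counts.

    Closed forms: the fraction of pairs appearing as univalent couples
    estimates ``1 - p_bound``; among bound pairs the rod fraction
    estimates ``exp(-lambda_extra)``, so ``lambda_extra = -log(rods /
    (rods + rings))``. All-ring data sit on the boundary (rate capped,
    flagged); all-rod data give lambda_extra = 0.
    """
    if len(cells) < 20:
        raise ValueError("need at least 20 cells for moment estimation")
    univ = float(np.mean([c.univalents for c in cells]))
    rods = float(np.mean([c.rods for c in cells]))
    rings = float(np.mean([c.rings for c in cells]))
    if n_pairs is None:
        n_pairs = round(univ / 2 + rods + rings)

    p_fail = min(1.0, univ / (2.0 * n_pairs)) if n_pairs else 0.0
    boundary = False
    bound_total = rods + rings
    if bound_total == 0:
        lam, boundary = 0.0, True
    elif rods == 0:
        lam, boundary = 20.0, True  # all rings: rate not identifiable, capped
    else:
        lam = -math.log(rods / bound_total)
    model = MeiosisModel(n_pairs=int(n_pairs), lambda_extra=lam,
                         p_obligate_fail=p_fail)
    return MomentFit(model=model, boundary=boundary)


def model_from_line_means(
    mean_chiasmata: float,
    mean_univalents: float,
    n_pairs: int = 21,
    n_telosome_pairs: int = 0,
    line_id: str = "sim",
) -> MeiosisModel:
    """Moment-match a model to printed per-line means.

    Solves ``p_bound = 1 - univ/(2 n)`` and ``mean = n_biv * p_bound *
    (2 - exp(-lambda)) + n_telo * p_bound`` for ``lambda_extra``
    (trans_factor fixed at 1; the fit absorbs any trans effect into
    p_obligate_fail and lambda_extra).
    """
    n_total = n_pairs + n_telosome_pairs
    s = 1.0 - mean_univalents / (2.0 * n_total)
    if not 0.0 < s <= 1.0:
        raise ValueError("inconsistent univalent mean")
    per_pair = (mean_chiasmata - n_telosome_pairs * s) / (n_pairs * s)
    q0 = 2.0 - per_pair
    if not 0.0 < q0 <= 1.0:
        raise ValueError("means outside the model's reachable range")
    return MeiosisModel(
        n_pairs=n_pairs, n_telosome_pairs=n_telosome_pairs,
        lambda_extra=-math.log(q0), p_obligate_fail=1.0 - s,
        line_id=line_id,
    )


def builtin_scenarios() -> dict[str, MeiosisModel]:
    """Named study-like scenarios, moment-matched to the published line means."""
    from . import reference

    df = reference.line_summaries().set_index("line_id")

    def from_row(line: str, n_pairs: int, n_telo: int) -> MeiosisModel:
        row = df.loc[line]
        return model_from_line_means(
            row["chiasmata_mean"], row["univalents_mean"],
            n_pairs=n_pairs, n_telosome_pairs=n_telo, line_id=line,
        )

    cs = from_row("CS", 21, 0)
    return {
        "CS-like": cs,
        "N3B-like": from_row("N3B", 20, 0),
        "Dt3BS-like": from_row("Dt3BS", 20, 1),
        "Dt3BL-like": from_row("Dt3BL", 20, 1),
        "cis-loss-1": replace(cs, cis_loss=1.0, line_id="cis1"),
    }


# ---------------------------------------------------------------------------
# Gene / FPKM / alignment-hit fixtures


def make_gene_fixture(
    bins: Sequence[DeletionBin],
    counts: Mapping[str, tuple[int, int, int]] | None = None,
    n_genes_per_bin: int = 40,
    fraction_expressed: float = 0.35,
    fraction_b_overexpressed: float = 0.19,
    seed: int | None = 0,
    n_stages: int = 4,
    n_replicates: int = 2,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Plant a gene table, an FPKM table and an alignment-hit table.

    Genes are placed uniformly within their bin's fraction-length
    interval. Per-copy FPKM is log-normal background; the planted
    expressed genes get one B-copy stage mean pushed above the FPKM
    threshold, the planted B-overexpressed subset additionally keeps A
    and D grand means below half of B, and all other genes keep an A
    grand mean above half of B so the fold-change rule fails.

    ``counts`` pins exact per-bin (mapped, expressed, B-overexpressed)
    counts — overexpressed must not exceed expressed, which must not
    exceed mapped; otherwise binomially realized fractions are used.
    Returns (genes, fpkm long-form, hits) DataFrames.
    """
    if rng is None:
        rng = np.random.default_rng(seed)

    gene_rows = []
    fpkm_rows = []
    hit_rows = []
    gene_no = 0
    for b in bins:
        if counts is not None:
            if b.name not in counts:
                raise ValueError(f"counts missing bin {b.name}")
            n_mapped, n_expr, n_over = counts[b.name]
            if not 0 <= n_over <= n_expr <= n_mapped:
                raise ValueError(
                    f"{b.name}: need overexpressed <= expressed <= mapped"
                )
        else:
            n_mapped = n_genes_per_bin
            n_expr = int(rng.binomial(n_mapped, fraction_expressed))
            n_over = int(rng.binomial(n_expr, fraction_b_overexpressed))

        for i in range(n_mapped):
            gene_no += 1
            gene = f"G{gene_no:05d}"
            expressed = i < n_expr
            overexpressed = i < n_over
            pos = float(rng.uniform(b.fl_low, b.fl_high))

            shape = (n_stages, n_replicates)
            noise = rng.lognormal(mean=0.0, sigma=0.3, size=(3,) + shape)
            if expressed:
                peak = float(rng.uniform(8.0, 50.0))
                b_mat = noise[1] * peak / noise[1].mean()
            else:
                level = float(rng.uniform(0.2, 4.0))
                b_mat = noise[1] * level
                b_mat = np.minimum(b_mat, 4.9)  # keep every stage mean < 5
            b_mean = b_mat.mean()
            if overexpressed:
                a_mat = noise[0] * (b_mean / 4.0) / noise[0].mean()
                d_mat = noise[2] * (b_mean / 4.0) / noise[2].mean()
            else:
                a_mat = noise[0] * (b_mean * 0.8) / noise[0].mean()
                d_mat = noise[2] * (b_mean * 0.7) / noise[2].mean()

            gene_rows.append({
                "gene": gene, "arm": b.arm, "bin": b.name, "fraction": pos,
                "expressed_planted": expressed,
                "overexpressed_planted": overexpressed,
            })
            for copy, mat in (("A", a_mat), ("B", b_mat), ("D", d_mat)):
                for st in range(n_stages):
                    for rep in range(n_replicates):
                        fpkm_rows.append({
                            "gene": gene, "copy": copy, "stage": st + 1,
                            "replicate": rep + 1,
                            "fpkm": float(mat[st, rep]),
                        })

            # one alignment hit per gene, passing for the expressed half
            if expressed:
                score = float(rng.uniform(520, 2000))
                ident = float(rng.uniform(42, 90))
                sim = float(rng.uniform(max(ident, 62), 99))
            else:
                which = int(rng.integers(3))  # which threshold to violate
                if which == 0:
                    score = float(rng.uniform(50, 500))
                    ident = float(rng.uniform(42, 90))
                    sim = float(rng.uniform(max(ident, 62), 99))
                elif which == 1:
                    score = float(rng.uniform(520, 2000))
                    ident = float(rng.uniform(5, 40))
                    sim = float(rng.uniform(62, 99))
                else:
                    score = float(rng.uniform(520, 2000))
                    sim = float(rng.uniform(20, 60))
                    ident = float(rng.uniform(5, sim))
            hit_rows.append({
                "query": f"model_{gene}", "target_gene": gene,
                "score": score, "identity_pct": ident, "similarity_pct": sim,
                "target_position": pos,
            })

    genes = pd.DataFrame(gene_rows)
    fpkm = pd.DataFrame(fpkm_rows)
    hits = pd.DataFrame(hit_rows)
    return genes, fpkm, hits
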