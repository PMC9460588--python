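"""Homoeologue-triad expression screening and candidate-gene filtering.

Hexaploid wheat carries three homoeologous copies (A, B, D subgenomes)
of most genes. For genes located in 3B deletion bins the screen asks:
is the B copy expressed in meiotic anthers (FPKM > 5 in at least one
stage), is it overexpressed relative to both homoeologues (fold change
> 2 against A and against D), and which copy of a triad is the most
expressed. Candidate hits from protein alignment are kept only above
score/identity/similarity cut-offs, and a copy-functionality triage
flags homoeologous copies accumulating non-neutral substitutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bins import DeletionBin
from ._round import round_half_up

__all__ = [
    "ExpressionTriad",
    "AlignmentHit",
    "CopyFunctionalityCall",
    "is_expressed",
    "overexpressed_on_B",
    "triad_max",
    "bin_expression_summary",
    "filter_hits",
    "functionality_triage",
    "read_fpkm_table",
]

COPIES = ("A", "B", "D")


@dataclass
class ExpressionTriad:
    """FPKM of the A/B/D copies of one gene over stages x replicates.

    ``fpkm`` maps a copy letter to an array of shape (n_stages,
    n_replicates); absent copies are simply missing from the mapping.
    Multiple same-subgenome copies should be averaged before
    construction.
    """

    gene_id_b: str
    fpkm: dict[str, np.ndarray]
    gene_id_a: str | None = None
    gene_id_d: str | None = None

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for copy, values in self.fpkm.items():
            if copy not in COPIES:
                raise ValueError(f"unknown subgenome copy {copy!r}")
            arr = np.atleast_2d(np.asarray(values, dtype=float))
            if arr.size == 0:
                raise ValueError(f"copy {copy} has no FPKM values")
            if np.any(arr < 0):
                raise ValueError(f"copy {copy} has negative FPKM values")
            clean[copy] = arr
        self.fpkm = clean

    def condition_means(self, copy: str) -> np.ndarray:
        """Per-stage FPKM means (replicates averaged first)."""
        return self.fpkm[copy].mean(axis=1)

    def grand_mean(self, copy: str) -> float:
        return float(self.fpkm[copy].mean())


def is_expressed(fpkm: np.ndarray | Sequence[Sequence[float]],
                 threshold: float = 5.0) -> bool:
    """Expressed iff any per-stage mean FPKM strictly exceeds the threshold.

    Replicates are averaged within each stage first; the comparison is
    strict (a stage mean exactly at the threshold does not count).
    """
    arr = np.atleast_2d(np.asarray(fpkm, dtype=float))
    if arr.size == 0 or np.all(np.isnan(arr)):
        raise ValueError("no FPKM values")
    stage_means = np.nanmean(arr, axis=1)
    return bool(np.any(stage_means > threshold))


def overexpressed_on_B(triad: ExpressionTriad, fold: float = 2.0,
                       pseudocount: float = 0.0) -> bool:
    """B-copy overexpression: grand-mean fold change > ``fold`` vs A and vs D.

    Genes lacking an A or D copy count as overexpressed (the comparison
    cannot contradict it); a zero homoeologue mean with a non-zero B mean
    likewise counts. A pseudocount may be added to both sides to damp
    near-zero denominators.
    """
    if "B" not in triad.fpkm:
        raise ValueError(f"{triad.gene_id_b}: B copy absent")
    b = triad.grand_mean("B") + pseudocount
    for other in ("A", "D"):
        if other not in triad.fpkm:
            continue
        o = triad.grand_mean(other) + pseudocount
        if o == 0.0:
            if b > 0.0:
                continue
            return False
        if b / o <= fold:
            return False
    return True


def triad_max(triad: ExpressionTriad) -> str:
    """The most expressed copy ("A"/"B"/"D"), or "tie" on exact ties.

    Grand-mean FPKM over all stages and replicates; needs at least two
    copies with values.
    """
    present = [c for c in COPIES if c in triad.fpkm]
    if len(present) < 2:
        raise ValueError(f"{triad.gene_id_b}: need at least two copies to compare")
    means = {c: triad.grand_mean(c) for c in present}
    best = max(means.values())
    winners = [c for c in present if means[c] == best]
    return winners[0] if len(winners) == 1 else "tie"


def bin_expression_summary(
    genes: pd.DataFrame,
    bins: Sequence[DeletionBin] | None = None,
) -> pd.DataFrame:
    """Per-bin expression summary with arm and grand totals.

    ``genes`` needs columns ``gene``, ``bin``, ``arm``, ``expressed``
    (bool) and optionally ``overexpressed_b`` (bool). Returns one row per
    bin plus ``Total <arm> Assigned`` rows and a ``Total Assigned`` row:
    genes mapped, genes expressed, percentage expressed (2 decimals,
    half-up; 0 with a flag for an empty bin) and genes overexpressed on
    B. When ``bins`` is given, rows follow that order and gene bin names
    must all be known.
    """
    required = {"gene", "bin", "arm", "expressed"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene table lacks columns {sorted(missing)}")
    if genes["bin"].isna().any():
        bad = genes.loc[genes["bin"].isna(), "gene"].tolist()
        raise ValueError(f"genes without a bin: {bad}")
    has_over = "overexpressed_b" in genes.columns

    if bins is not None:
        order = [(b.name, b.arm) for b in bins]
        known = {b.name for b in bins}
        unknown = sorted(set(genes["bin"]) - known)
        if unknown:
            raise ValueError(f"genes assigned to unknown bins: {unknown}")
    else:
        order = (
            genes[["bin", "arm"]].drop_duplicates().itertuples(index=False, name=None)
        )
        order = list(order)

    rows = []
    for bin_name, arm in order:
        sub = genes[genes["bin"] == bin_name]
        n_mapped = len(sub)
        n_expr = int(sub["expressed"].sum())
        empty = n_mapped == 0
        pct = 0.0 if empty else round_half_up(100.0 * n_expr / n_mapped, 2)
        row = {
            "arm": arm, "bin": bin_name, "n_mapped": n_mapped,
            "n_expressed": n_expr, "pct_expressed": pct, "empty": empty,
        }
        if has_over:
            row["n_overexpressed_b"] = int(sub["overexpressed_b"].sum())
        rows.append(row)
    out = pd.DataFrame(rows)

    def total_row(label: str, sub: pd.DataFrame) -> dict:
        n_mapped = int(sub["n_mapped"].sum())
        n_expr = int(sub["n_expressed"].sum())
        row = {
            "arm": label, "bin": label, "n_mapped": n_mapped,
            "n_expressed": n_expr,
            "pct_expressed": 0.0 if n_mapped == 0
            else round_half_up(100.0 * n_expr / n_mapped, 2),
            "empty": n_mapped == 0,
        }
        if has_over:
            row["n_overexpressed_b"] = int(sub["n_overexpressed_b"].sum())
        return row

    totals = []
    for arm in dict.fromkeys(out["arm"]):
        totals.append(total_row(f"Total {arm} Assigned", out[out["arm"] == arm]))
    totals.append(total_row("Total Assigned", out))
    return pd.concat([out, pd.DataFrame(totals)], ignore_index=True)


# ---------------------------------------------------------------------------
# Alignment-hit filtering


@dataclass(frozen=True)
class AlignmentHit:
    """One protein-alignment hit of a query against a target gene model."""

    query: str
    target_gene: str
    score: float
    identity_pct: float
    similarity_pct: float
    target_position: float | None = None

    def __post_init__(self) -> None:
        for name in ("identity_pct", "similarity_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")


def filter_hits(
    hits: Iterable[AlignmentHit],
    score_min: float = 500.0,
    id_min: float = 40.0,
    sim_min: float = 60.0,
) -> list[AlignmentHit]:
    """Hits strictly above all three cut-offs, input order preserved."""
    return [
        h for h in hits
        if h.score > score_min and h.identity_pct > id_min
        and h.similarity_pct > sim_min
    ]


# ---------------------------------------------------------------------------
# Copy-functionality triage


@dataclass(frozen=True)
class CopyFunctionalityCall:
    gene: str
    copy: str                      # "A", "B" or "D"
    status: str                    # "functional" or "doubtful"
    evidence: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.status == "doubtful" and not self.evidence:
            raise ValueError("a doubtful call requires evidence")


GAP = "-"
STOP = "*"


def _check_lengths(gene: str, seqs: Mapping[str, str], length: int) -> None:
    for name, s in seqs.items():
        if len(s) != length:
            raise ValueError(
                f"{gene}: aligned copy {name} has length {len(s)}, expected {length}"
            )


def functionality_triage(
    gene: str,
    diploid_a: str,
    diploid_d: str,
    polyploid_a: Mapping[str, str],
    polyploid_b: Mapping[str, str],
    polyploid_d: Mapping[str, str],
    recurrence: float = 0.5,
) -> list[CopyFunctionalityCall]:
    """Flag homoeologous copies with putative loss-of-function changes.

    All sequences are rows of one gapped protein multiple alignment
    (equal length). The copies in the diploid progenitors are assumed
    functional, so:

    1. positions where the two diploid copies differ are masked as
       neutral;
    2. a polyploid A (resp. D) copy deviating from the diploid A (resp.
       D) at an unmasked position, recurrently across more than
       ``recurrence`` of the varieties, flags that copy;
    3. a B copy deviating from the A/D consensus (positions where the
       two diploids agree) under the same recurrence rule flags B;
    4. a premature stop, or a gap, at an unmasked conserved position
       always flags the carrying copy.
    """
    if not 0.0 <= recurrence <= 1.0:
        raise ValueError("recurrence must lie in [0, 1]")
    length = len(diploid_a)
    _check_lengths(gene, {"diploid_D": diploid_d}, length)
    _check_lengths(gene, polyploid_a, length)
    _check_lengths(gene, polyploid_b, length)
    _check_lengths(gene, polyploid_d, length)

    masked = {i for i in range(length) if diploid_a[i] != diploid_d[i]}
    unmasked = [i for i in range(length) if i not in masked]

    def last_residue(seq: str) -> int:
        for i in range(len(seq) - 1, -1, -1):
            if seq[i] != GAP:
                return i
        return -1

    def deviations(seq: str, ref: Mapping[int, str]) -> tuple[list[str], list[str]]:
        """(recurrent-type substitution positions, always-flag positions)."""
        subs: list[str] = []
        hard: list[str] = []
        last = last_residue(seq)
        for i, expected in ref.items():
            got = seq[i]
            if got == expected:
                continue
            if got == STOP and i < last:
                hard.append(f"premature stop at {i}")
            elif got == GAP:
                hard.append(f"gap at conserved position {i}")
            else:
                subs.append(f"substitution {expected}->{got} at {i}")
        return subs, hard

    calls: list[CopyFunctionalityCall] = []
    panels = [
        ("A", polyploid_a, {i: diploid_a[i] for i in unmasked}),
        ("D", polyploid_d, {i: diploid_d[i] for i in unmasked}),
        ("B", polyploid_b, {i: diploid_a[i] for i in unmasked}),  # A/D consensus
    ]
    for copy, panel, ref in panels:
        if not panel:
            continue
        n_var = len(panel)
        sub_counts: dict[str, int] = {}
        hard_evidence: list[str] = []
        for variety, seq in panel.items():
            subs, hard = deviations(seq, ref)
            for s in subs:
                sub_counts[s] = sub_counts.get(s, 0) + 1
            hard_evidence.extend(f"{variety}: {h}" for h in hard)
        recurrent = [
            f"{s} in {c}/{n_var} varieties"
            for s, c in sorted(sub_counts.items())
            if c / n_var > recurrence
        ]
        evidence = tuple(recurrent + hard_evidence)
        calls.append(CopyFunctionalityCall(
            gene=gene, copy=copy,
            status="doubtful" if evidence else "functional",
            evidence=evidence,
        ))
    return calls


# ---------------------------------------------------------------------------
# FPKM table I/O: gene, copy, stage, replicate, fpkm (TSV)


def read_fpkm_table(path) -> dict[str, ExpressionTriad]:
    """Read a long-form FPKM TSV into triads keyed by gene id."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "copy", "stage", "replicate", "fpkm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"FPKM table lacks columns {sorted(missing)}")
    triads: dict[str, ExpressionTriad] = {}
    for gene, sub in df.groupby("gene", sort=True):
        fpkm: dict[str, np.ndarray] = {}
        for copy, csub in sub.groupby("copy"):
            mat = csub.pivot_table(index="stage", columns="replicate",
                                   values="fpkm", aggfunc="mean")
            fpkm[str(copy)] = mat.to_numpy(dtype=float)
        triads[str(gene)] = ExpressionTriad(gene_id_b=str(gene), fpkm=fpkm)
    return triads
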