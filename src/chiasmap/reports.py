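"""Pipeline orchestration and tabular report writers.

Two entry points mirror the analysis: ``run_chiasma_pipeline`` goes from
a per-cell configuration table to line summaries, all-pairs rank tests,
compact letter displays and (when deletion-line karyotypes are present)
the per-arm chiasma-drop attribution; ``run_expression_pipeline`` goes
from gene/FPKM tables to the per-bin expression summary and the
candidate-triad report. All outputs are TSV; display rounding is
half-up to 2 decimals, internal computation is unrounded.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import bins as binmod
from . import expression as expr
from . import stats as st
from ._round import format_half_up
from .scoring import (
    LineKaryotype, LineSummary, PMCConfiguration,
    read_cell_table, score_chiasmata, summarize_line,
)

__all__ = [
    "RunConfig",
    "run_chiasma_pipeline",
    "run_expression_pipeline",
    "read_karyotype_table",
    "summary_table",
    "pairwise_table",
    "letters_table",
    "drops_table",
    "plot_chiasmata_by_line",
]

REPORT_TRAITS = ("chiasmata", "univalents", "bivalents", "rods", "rings",
                 "multivalents")


@dataclass
class RunConfig:
    """Thresholds and paths driving a pipeline run."""

    cells: str | None = None
    karyotypes: str | None = None
    genes: str | None = None
    fpkm: str | None = None
    hits: str | None = None
    outdir: str = "chiasmap_out"
    alpha: float = 0.05
    bonferroni_m: int | None = None
    fpkm_threshold: float = 5.0
    fold_threshold: float = 2.0
    score_min: float = 500.0
    id_min: float = 40.0
    sim_min: float = 60.0
    cis_delta: float = 1.0
    reference_line: str = "CS"
    seed: int = 0
    weights: dict[str, int] | None = None

    def __post_init__(self) -> None:
        for name in ("alpha", "fpkm_threshold", "fold_threshold",
                     "score_min", "id_min", "sim_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def read_karyotype_table(path: str | Path) -> dict[str, LineKaryotype]:
    """TSV with columns line_id, total_units, arm, fraction_retained."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"line_id", "total_units", "arm", "fraction_retained"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"karyotype table lacks columns {sorted(missing)}")
    return {
        str(r.line_id): LineKaryotype(
            line_id=str(r.line_id), total_units=int(r.total_units),
            arm=str(r.arm), fraction_retained=float(r.fraction_retained),
        )
        for r in df.itertuples()
    }


# ---------------------------------------------------------------------------
# Report tables


def _fmt_ms(mean: float, sd: float) -> str:
    return f"{format_half_up(mean)} ± {format_half_up(sd)}"


def summary_table(summaries: Sequence[LineSummary]) -> pd.DataFrame:
    """Line-per-row summary: n, mean +- sd per trait, letters when present."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {"line": s.line_id, "n": s.n_cells}
        for t in REPORT_TRAITS:
            cell = _fmt_ms(s.traits[t].mean, s.traits[t].sd)
            letters = s.letter_groups.get(t, "")
            if letters is None:
                letters = "NA"
            row[t] = f"{cell}{letters}" if letters else cell
        if s.unit_mismatches:
            row["unit_mismatches"] = ",".join(s.unit_mismatches)
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_table(results: Sequence[st.PairwiseResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "trait": r.trait, "line_a": r.line_a, "line_b": r.line_b,
            "statistic": r.statistic, "p_raw": r.p_raw,
            "p_adj": r.p_adjusted, "significant": r.significant,
        }
        for r in results
    ])


def letters_table(assignments: Sequence[st.LetterAssignment]) -> pd.DataFrame:
    lines = sorted({l for a in assignments for l in a.letters})
    rows = []
    for line in lines:
        row: dict[str, object] = {"line": line}
        for a in assignments:
            v = a.letters.get(line)
            row[a.trait] = "NA" if v is None else v
        rows.append(row)
    return pd.DataFrame(rows)


def drops_table(attribution: binmod.DropAttribution) -> pd.DataFrame:
    rows = [
        {
            "arm": attribution.arm, "from_line": s.from_line,
            "to_line": s.to_line, "lost_bins": ";".join(s.lost_bins),
            "delta_mean_chiasmata": s.delta_mean,
            "step_significant": s.step_significant,
            "vs_reference_significant": s.vs_reference_significant,
            "implicated": s.implicated,
        }
        for s in attribution.steps
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipelines


def _log(stage: str, t0: float) -> None:
    print(f"[chiasmap] {stage} ({time.perf_counter() - t0:.2f}s)", file=sys.stderr)


def run_chiasma_pipeline(config: RunConfig) -> dict[str, Path]:
    """Per-cell table -> line summaries, pairwise tests, letters, drops."""
    if config.cells is None:
        raise ValueError("config.cells is required")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    cells = read_cell_table(config.cells)
    karyotypes = (read_karyotype_table(config.karyotypes)
                  if config.karyotypes else {})
    by_line: dict[str, list[PMCConfiguration]] = {}
    for c in cells:
        by_line.setdefault(c.line_id, []).append(c)
    summaries = {
        line: summarize_line(cs, karyotypes.get(line), weights=config.weights)
        for line, cs in by_line.items()
    }
    _log(f"scored {len(cells)} cells in {len(by_line)} lines", t0)

    outputs: dict[str, Path] = {}
    assignments: list[st.LetterAssignment] = []
    all_pairwise: list[st.PairwiseResult] = []
    if len(by_line) >= 3:
        for trait in REPORT_TRAITS:
            groups = {
                line: _trait_values(cs, trait, config.weights)
                for line, cs in by_line.items()
            }
            pw = st.dunn_pairwise(groups, alpha=config.alpha, trait=trait)
            all_pairwise.extend(pw)
            means = {line: summaries[line].traits[trait].mean for line in by_line}
            assign = st.letter_groups(pw, means, trait=trait)
            assignments.append(assign)
            for line in by_line:
                summaries[line].letter_groups[trait] = assign.letters[line]
        _log("pairwise tests and letter groups", t0)

    ordered = sorted(summaries.values(), key=lambda s: s.line_id)
    outputs["summary"] = outdir / "line_summary.tsv"
    summary_table(ordered).to_csv(outputs["summary"], sep="\t", index=False)
    if all_pairwise:
        outputs["pairwise"] = outdir / "pairwise.tsv"
        pairwise_table(all_pairwise).to_csv(outputs["pairwise"], sep="\t", index=False)
        outputs["letters"] = outdir / "letters.tsv"
        letters_table(assignments).to_csv(outputs["letters"], sep="\t", index=False)

    # drop attribution per arm, when karyotypes describe a deletion series
    if karyotypes and config.reference_line in by_line:
        drop_frames = []
        for arm in ("3BS", "3BL"):
            attribution = _attribute_arm(by_line, summaries, karyotypes, arm, config)
            if attribution is not None:
                drop_frames.append(drops_table(attribution))
        if drop_frames:
            outputs["drops"] = outdir / "drops.tsv"
            pd.concat(drop_frames, ignore_index=True).to_csv(
                outputs["drops"], sep="\t", index=False)
            _log("drop attribution", t0)
    return outputs


def _trait_values(cells: Sequence[PMCConfiguration], trait: str,
                  weights) -> list[float]:
    if trait == "chiasmata":
        return [score_chiasmata(c, weights) for c in cells]
    if trait == "multivalents":
        return [float(c.multivalents) for c in cells]
    if trait == "bivalents":
        return [float(c.bivalents) for c in cells]
    return [float(getattr(c, trait)) for c in cells]


def _attribute_arm(by_line, summaries, karyotypes, arm, config):
    series_lines = sorted(
        (
            k for k in karyotypes.values()
            if k.arm == arm and k.line_id in by_line and k.fraction_retained < 1.0
        ),
        key=lambda k: -k.fraction_retained,
    )
    if not series_lines:
        return None
    arm_letter = arm[-1]
    line_defs = [
        binmod.DeletionLineDef(name=k.line_id, arm=arm_letter,
                               fraction_retained=k.fraction_retained)
        for k in series_lines if 0.0 < k.fraction_retained < 1.0
    ]
    if not line_defs:
        return None
    bins = binmod.build_bins(line_defs)
    ref = config.reference_line
    series = [
        (k.line_id, k.fraction_retained,
         summaries[k.line_id].traits["chiasmata"].mean)
        for k in series_lines
    ]
    samples = {
        line: _trait_values(by_line[line], "chiasmata", config.weights)
        for line in by_line
    }
    return binmod.attribute_drops_from_samples(
        series=series,
        reference=(ref, summaries[ref].traits["chiasmata"].mean),
        samples=samples, bins=bins, arm=arm_letter, alpha=config.alpha,
        bonferroni_m=config.bonferroni_m,
    )


def run_expression_pipeline(config: RunConfig) -> dict[str, Path]:
    """Gene + FPKM tables -> per-bin summary and triad report."""
    if config.genes is None or config.fpkm is None:
        raise ValueError("config.genes and config.fpkm are required")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    genes = pd.read_csv(config.genes, sep="\t", comment="#")
    triads = expr.read_fpkm_table(config.fpkm)
    missing = sorted(set(genes["gene"]) - set(triads))
    if missing:
        raise ValueError(f"genes without FPKM data: {missing[:10]}")

    flags = []
    for g in genes["gene"]:
        triad = triads[g]
        expressed = ("B" in triad.fpkm
                     and expr.is_expressed(triad.fpkm["B"], config.fpkm_threshold))
        over = ("B" in triad.fpkm
                and expr.overexpressed_on_B(triad, config.fold_threshold))
        try:
            top = expr.triad_max(triad)
        except ValueError:
            top = ""
        flags.append((expressed, over, top))
    genes = genes.copy()
    genes["expressed"] = [f[0] for f in flags]
    genes["overexpressed_b"] = [f[1] for f in flags]
    genes["most_expressed_copy"] = [f[2] for f in flags]
    _log(f"classified {len(genes)} triads", t0)

    outputs: dict[str, Path] = {}
    summary = expr.bin_expression_summary(genes)
    outputs["bin_summary"] = outdir / "bin_expression.tsv"
    summary.to_csv(outputs["bin_summary"], sep="\t", index=False)

    triad_report = genes[["gene", "arm", "bin", "expressed",
                          "overexpressed_b", "most_expressed_copy"]]
    outputs["triads"] = outdir / "triads.tsv"
    triad_report.to_csv(outputs["triads"], sep="\t", index=False)

    if config.hits:
        raw = pd.read_csv(config.hits, sep="\t", comment="#")
        hits = [
            expr.AlignmentHit(
                query=str(r.query), target_gene=str(r.target_gene),
                score=float(r.score), identity_pct=float(r.identity_pct),
                similarity_pct=float(r.similarity_pct),
            )
            for r in raw.itertuples()
        ]
        kept = expr.filter_hits(hits, config.score_min, config.id_min,
                                config.sim_min)
        outputs["hits"] = outdir / "hits_filtered.tsv"
        pd.DataFrame([h.__dict__ for h in kept]).to_csv(
            outputs["hits"], sep="\t", index=False)
    _log("expression reports written", t0)
    return outputs


def plot_chiasmata_by_line(
    summaries: Sequence[LineSummary],
    path: str | Path,
    reference_lines: Sequence[str] = ("CS", "N3B", "Dt3BS"),
) -> Path:
    """Mean chiasmata by line with horizontal guides at reference means."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [s.line_id for s in summaries]
    means = [s.traits["chiasmata"].mean for s in summaries]
    sds = [s.traits["chiasmata"].sd for s in summaries]
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(names)), 4))
    ax.errorbar(range(len(names)), means, yerr=sds, fmt="o", capsize=3)
    for ref in reference_lines:
        match = [s for s in summaries if s.line_id == ref]
        if match:
            ax.axhline(match[0].traits["chiasmata"].mean, ls="--", lw=0.8,
                       alpha=0.6)
            ax.annotate(ref, (len(names) - 0.5, match[0].traits["chiasmata"].mean),
                        fontsize=8, va="bottom")
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels(names, rotation=60, ha="right", fontsize=8)
    ax.set_ylabel("mean chiasmata per cell")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
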