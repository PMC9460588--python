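"""Chiasma scoring of metaphase-I pollen-mother-cell configurations.

At metaphase I each homologous association is classified by shape:
univalents carry no chiasma, a rod bivalent one (one arm bound), a ring
bivalent two (both arms bound), and trivalents/quadrivalents are scored
with three and four chiasmata respectively. Per-cell configuration counts
therefore convert linearly into a chiasma count, and per-line means over
a sample of cells (50 in the standard protocol) summarize recombination
in each karyotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PMCConfiguration",
    "LineKaryotype",
    "TraitStats",
    "LineSummary",
    "DEFAULT_WEIGHTS",
    "score_chiasmata",
    "chromosome_units",
    "summarize_line",
    "read_cell_table",
    "write_cell_table",
    "summaries_to_frame",
]

#: Chiasmata contributed per configuration class.
DEFAULT_WEIGHTS: dict[str, int] = {
    "univalents": 0,
    "rods": 1,
    "rings": 2,
    "trivalents": 3,
    "quadrivalents": 4,
}

#: Chromosome units bound up in one configuration of each class
#: (a telocentric chromosome counts as one unit like any other).
UNIT_WEIGHTS: dict[str, int] = {
    "univalents": 1,
    "rods": 2,
    "rings": 2,
    "bivalents": 2,  # pooled rods+rings, for rows reported that way
    "trivalents": 3,
    "quadrivalents": 4,
}

_COUNT_FIELDS = ("univalents", "rods", "rings", "trivalents", "quadrivalents")


@dataclass(frozen=True)
class PMCConfiguration:
    """Configuration counts of one pollen mother cell at metaphase I."""

    line_id: str
    cell_id: str
    univalents: int = 0
    rods: int = 0
    rings: int = 0
    trivalents: int = 0
    quadrivalents: int = 0

    def __post_init__(self) -> None:
        for name in _COUNT_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise ValueError(f"{name} must be an integer, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")

    @property
    def bivalents(self) -> int:
        return self.rods + self.rings

    @property
    def multivalents(self) -> int:
        return self.trivalents + self.quadrivalents

    def counts(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in _COUNT_FIELDS}


@dataclass(frozen=True)
class LineKaryotype:
    """Declared karyotype of a line.

    ``total_units`` is 2n in chromosome units with telosomes counting one
    unit each ("40+2t" is 42 units). ``fraction_retained`` is the fraction
    length of the deleted arm still present, measured from the centromere
    (1.0 for an intact arm, 0.0 for a fully absent one).
    """

    line_id: str
    total_units: int
    arm: str = "none"  # one of {"3BS", "3BL", "both", "none"}
    fraction_retained: float = 1.0

    def __post_init__(self) -> None:
        if self.arm not in {"3BS", "3BL", "both", "none"}:
            raise ValueError(f"unknown arm {self.arm!r}")
        if not 0.0 <= self.fraction_retained <= 1.0:
            raise ValueError("fraction_retained must lie in [0, 1]")


def score_chiasmata(
    config: PMCConfiguration | Mapping[str, float],
    weights: Mapping[str, float] | None = None,
) -> float:
    """Chiasma count of one cell (or of a row of mean counts).

    Accepts either a :class:`PMCConfiguration` or any mapping with keys
    among ``univalents, rods, rings, trivalents, quadrivalents`` — mean
    configuration counts score the mean chiasma count, by linearity.
    """
    w = dict(DEFAULT_WEIGHTS)
    if weights is not None:
        w.update(weights)
    counts = config.counts() if isinstance(config, PMCConfiguration) else config
    for name, value in counts.items():
        if name not in w:
            raise ValueError(f"unknown configuration class {name!r}")
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")
    return float(sum(w[name] * value for name, value in counts.items()))


def chromosome_units(config: PMCConfiguration | Mapping[str, float]) -> float:
    """Chromosome units accounted for by a configuration.

    ``univalents + 2(rods+rings) + 3 trivalents + 4 quadrivalents``; for a
    well-formed cell this equals the line's declared 2n in units.
    """
    counts = config.counts() if isinstance(config, PMCConfiguration) else config
    unknown = set(counts) - set(UNIT_WEIGHTS)
    if unknown:
        raise ValueError(f"unknown configuration classes {sorted(unknown)}")
    return float(sum(UNIT_WEIGHTS[name] * value for name, value in counts.items()))


@dataclass(frozen=True)
class TraitStats:
    mean: float
    sd: float


@dataclass
class LineSummary:
    """Per-line summary of configuration and chiasma counts."""

    line_id: str
    n_cells: int
    traits: dict[str, TraitStats]
    letter_groups: dict[str, str | None] = field(default_factory=dict)
    unit_mismatches: list[str] = field(default_factory=list)

    def mean(self, trait: str) -> float:
        return self.traits[trait].mean

    def sd(self, trait: str) -> float:
        return self.traits[trait].sd


_SUMMARY_TRAITS = ("chiasmata", "univalents", "bivalents", "rods", "rings",
                   "trivalents", "quadrivalents", "multivalents")


def summarize_line(
    cells: Sequence[PMCConfiguration],
    karyotype: LineKaryotype | None = None,
    weights: Mapping[str, float] | None = None,
) -> LineSummary:
    """Means and sample SDs (n-1 denominator) of the scored traits.

    Chiasmata are scored per cell first, then averaged. When a karyotype
    is given, each cell's chromosome-unit accounting is checked against
    the declared total; mismatching cell ids are reported on the summary
    (flagged, not fatal).
    """
    if not cells:
        raise ValueError("summarize_line requires at least one cell")
    line_ids = {c.line_id for c in cells}
    if len(line_ids) != 1:
        raise ValueError(f"cells from multiple lines: {sorted(line_ids)}")

    values: dict[str, list[float]] = {t: [] for t in _SUMMARY_TRAITS}
    mismatches: list[str] = []
    for cell in cells:
        values["chiasmata"].append(score_chiasmata(cell, weights))
        values["univalents"].append(cell.univalents)
        values["bivalents"].append(cell.bivalents)
        values["rods"].append(cell.rods)
        values["rings"].append(cell.rings)
        values["trivalents"].append(cell.trivalents)
        values["quadrivalents"].append(cell.quadrivalents)
        values["multivalents"].append(cell.multivalents)
        if karyotype is not None and chromosome_units(cell) != karyotype.total_units:
            mismatches.append(cell.cell_id)

    n = len(cells)
    traits = {}
    for trait, xs in values.items():
        mean = sum(xs) / n
        if n > 1:
            sd = math.sqrt(sum((x - mean) ** 2 for x in xs) / (n - 1))
        else:
            sd = 0.0
        traits[trait] = TraitStats(mean=mean, sd=sd)
    return LineSummary(line_id=line_ids.pop(), n_cells=n, traits=traits,
                       unit_mismatches=mismatches)


# ---------------------------------------------------------------------------
# Tab-delimited I/O

_CELL_COLUMNS = ["line_id", "cell_id", "univ", "rod", "ring", "triv", "quad"]


def read_cell_table(path: str | Path) -> list[PMCConfiguration]:
    """Read a per-cell configuration table.

    Tab-delimited with header ``line_id cell_id univ rod ring triv quad``;
    lines starting with ``#`` are comments. Malformed rows raise a
    ``ValueError`` naming the offending line number.
    """
    path = Path(path)
    cells: list[PMCConfiguration] = []
    with path.open() as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                if header != _CELL_COLUMNS:
                    raise ValueError(
                        f"{path}:{lineno}: expected header {_CELL_COLUMNS}, got {header}"
                    )
                continue
            if len(fields) != len(_CELL_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(_CELL_COLUMNS)} fields")
            try:
                cells.append(
                    PMCConfiguration(
                        line_id=fields[0],
                        cell_id=fields[1],
                        univalents=int(fields[2]),
                        rods=int(fields[3]),
                        rings=int(fields[4]),
                        trivalents=int(fields[5]),
                        quadrivalents=int(fields[6]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
        if header is None:
            raise ValueError(f"{path}: empty cell table")
    if not cells:
        raise ValueError(f"{path}: no data rows")
    return cells


def write_cell_table(cells: Iterable[PMCConfiguration], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_CELL_COLUMNS) + "\n")
        for c in cells:
            fh.write(
                f"{c.line_id}\t{c.cell_id}\t{c.univalents}\t{c.rods}\t"
                f"{c.rings}\t{c.trivalents}\t{c.quadrivalents}\n"
            )


def summaries_to_frame(
    summaries: Sequence[LineSummary],
    pool_multivalents: bool = True,
) -> pd.DataFrame:
    """Tabulate line summaries, one row per line.

    With ``pool_multivalents`` the trivalent and quadrivalent classes are
    pooled into a single multivalent column (the published presentation);
    otherwise they are kept separate.
    """
    if pool_multivalents:
        traits = ("chiasmata", "univalents", "bivalents", "rods", "rings",
                  "multivalents")
    else:
        traits = ("chiasmata", "univalents", "bivalents", "rods", "rings",
                  "trivalents", "quadrivalents")
    rows = []
    for s in summaries:
        row: dict[str, object] = {"line_id": s.line_id, "n_cells": s.n_cells}
        for t in traits:
            row[f"{t}_mean"] = s.traits[t].mean
            row[f"{t}_sd"] = s.traits[t].sd
            if s.letter_groups.get(t) is not None:
                row[f"{t}_letters"] = s.letter_groups[t]
        rows.append(row)
    return pd.DataFrame(rows)
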