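"""Deletion-bin construction and chiasma-drop attribution.

A terminal deletion line is named by the arm and the fraction length (FL)
of the arm it retains, measured from the centromere: 3BS4-0.55 keeps the
proximal 55% of the short arm. Sorting the breakpoints of all deletion
lines of one arm partitions the arm into deletion bins — half-open FL
intervals delimited by two successive breakpoints, plus a centromeric bin
(C- prefix) below the smallest breakpoint and a terminal bin closing at
1.00. A bin is named after the line whose breakpoint forms its proximal
edge. Features localize to exactly one bin; phenotypic effects along a
nested deletion series are attributed to the bin newly lost at the step
where the phenotype drops significantly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "DeletionLineDef",
    "DeletionBin",
    "DropStep",
    "DropAttribution",
    "parse_deletion_line",
    "format_deletion_line",
    "build_bins",
    "assign_to_bin",
    "bin_sizes",
    "attribute_drops",
    "read_bin_table",
    "write_bin_table",
]

_LINE_NAME_RE = re.compile(r"^(?P<stem>.+?(?P<arm>[SL])\d+)-(?P<fl>\d\.\d{2})$")


@dataclass(frozen=True)
class DeletionLineDef:
    """A terminal deletion line: arm and fraction of the arm retained."""

    name: str
    arm: str  # "S" or "L"
    fraction_retained: float

    def __post_init__(self) -> None:
        if self.arm not in {"S", "L"}:
            raise ValueError(f"arm must be 'S' or 'L', got {self.arm!r}")
        if not 0.0 <= self.fraction_retained <= 1.0:
            raise ValueError("fraction_retained must lie in [0, 1]")


def parse_deletion_line(name: str) -> DeletionLineDef:
    """Parse a line name like ``3BS4-0.55`` (fraction encoded to 2 decimals)."""
    m = _LINE_NAME_RE.match(name)
    if m is None:
        raise ValueError(f"cannot parse deletion-line name {name!r}")
    return DeletionLineDef(name=name, arm=m.group("arm"),
                           fraction_retained=float(m.group("fl")))


def format_deletion_line(line: DeletionLineDef) -> str:
    return line.name


@dataclass(frozen=True)
class DeletionBin:
    """Half-open fraction-length interval [fl_low, fl_high) on one arm.

    The terminal bin is closed at 1.00. Physical (Mb) bounds or a size
    are optional; fraction length is cytological and not proportional
    to Mb, so physical sizes are supplied, not interpolated.
    """

    name: str
    arm: str
    fl_low: float
    fl_high: float
    phys_low: float | None = None
    phys_high: float | None = None
    size_mb: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.fl_low < self.fl_high <= 1.0):
            raise ValueError(f"invalid bin interval [{self.fl_low}, {self.fl_high})")

    def contains(self, fraction: float) -> bool:
        if self.fl_high == 1.0:
            return self.fl_low <= fraction <= 1.0
        return self.fl_low <= fraction < self.fl_high

    @property
    def size(self) -> float | None:
        if self.size_mb is not None:
            return self.size_mb
        if self.phys_low is not None and self.phys_high is not None:
            return self.phys_high - self.phys_low
        return None


def build_bins(
    lines: Iterable[DeletionLineDef | str],
    include_centromeric: bool = True,
) -> list[DeletionBin]:
    """Deletion bins defined by a set of deletion lines, both arms.

    Breakpoints of each arm are sorted; each pair of successive
    breakpoints yields a bin named ``<proximal line>-<distal fraction>``,
    the terminal bin closes at 1.00, and (optionally) a centromeric
    ``C-<line>-<fraction>`` bin covers [0, smallest breakpoint).
    Telosome entries (fraction 0 or 1) only close the arm and produce no
    interior breakpoint. Input order is irrelevant.
    """
    defs = [parse_deletion_line(l) if isinstance(l, str) else l for l in lines]
    bins: list[DeletionBin] = []
    for arm in ("S", "L"):
        arm_defs = [d for d in defs if d.arm == arm and 0.0 < d.fraction_retained < 1.0]
        if not arm_defs:
            continue
        by_fl = sorted(arm_defs, key=lambda d: d.fraction_retained)
        fls = [d.fraction_retained for d in by_fl]
        if len(set(fls)) != len(fls):
            dupes = sorted({f for f in fls if fls.count(f) > 1})
            raise ValueError(f"duplicate breakpoints on arm {arm}: {dupes}")
        if include_centromeric:
            first = by_fl[0]
            bins.append(DeletionBin(
                name=f"C-{first.name}", arm=arm,
                fl_low=0.0, fl_high=first.fraction_retained,
            ))
        for prox, dist in zip(by_fl, by_fl[1:]):
            bins.append(DeletionBin(
                name=f"{prox.name}-{dist.fraction_retained:.2f}", arm=arm,
                fl_low=prox.fraction_retained, fl_high=dist.fraction_retained,
            ))
        last = by_fl[-1]
        bins.append(DeletionBin(
            name=f"{last.name}-1.00", arm=arm,
            fl_low=last.fraction_retained, fl_high=1.0,
        ))
    return bins


def assign_to_bin(
    position: float,
    arm: str,
    bins: Sequence[DeletionBin],
    physical: bool = False,
) -> DeletionBin:
    """The unique bin containing a position on an arm.

    ``position`` is a fraction length in [0, 1] by default, or an Mb
    coordinate with ``physical=True`` (requires physical bounds). Bins
    are half-open at the distal edge except the terminal bin.
    """
    arm_bins = [b for b in bins if b.arm == arm]
    if not arm_bins:
        raise ValueError(f"no bins on arm {arm!r}")
    if physical:
        for b in sorted(arm_bins, key=lambda b: b.phys_low if b.phys_low is not None else 0.0):
            if b.phys_low is None or b.phys_high is None:
                raise ValueError(f"bin {b.name} lacks physical bounds")
            is_last = b.phys_high == max(x.phys_high for x in arm_bins)
            if b.phys_low <= position < b.phys_high or (is_last and position == b.phys_high):
                return b
        raise ValueError(f"position {position} Mb outside arm {arm}")
    if not 0.0 <= position <= 1.0:
        raise ValueError(f"fraction-length position {position} outside [0, 1]")
    for b in arm_bins:
        if b.contains(position):
            return b
    raise ValueError(f"position {position} not covered by bins on arm {arm}")


def bin_sizes(bins: Sequence[DeletionBin]) -> tuple[dict[str, float], dict[str, float]]:
    """Per-bin physical sizes (Mb) and per-arm totals.

    Every bin must carry a size or physical bounds.
    """
    per_bin: dict[str, float] = {}
    per_arm: dict[str, float] = {}
    for b in bins:
        size = b.size
        if size is None:
            raise ValueError(f"bin {b.name} has no physical size")
        per_bin[b.name] = size
        per_arm[b.arm] = per_arm.get(b.arm, 0.0) + size
    return per_bin, per_arm


# ---------------------------------------------------------------------------
# Drop attribution along a nested deletion series


@dataclass(frozen=True)
class DropStep:
    """One step of a nested deletion series: the newly lost interval."""

    from_line: str
    to_line: str
    lost_bins: tuple[str, ...]
    delta_mean: float        # mean chiasmata change (to - from)
    step_significant: bool
    vs_reference_significant: bool

    @property
    def implicated(self) -> bool:
        return self.step_significant and self.vs_reference_significant


@dataclass(frozen=True)
class DropAttribution:
    arm: str
    steps: tuple[DropStep, ...]
    implicated_bins: tuple[str, ...] = field(default=())


def attribute_drops(
    series: Sequence[tuple[str, float, float]],
    reference: tuple[str, float],
    significant: Callable[[str, str], bool] | Mapping[frozenset, bool],
    bins: Sequence[DeletionBin],
    arm: str,
) -> DropAttribution:
    """Attribute chiasma drops along a nested deletion series to bins.

    ``series`` lists ``(line, fraction_retained, mean_chiasmata)`` ordered
    by strictly decreasing fraction retained; it may end with the line
    missing the whole arm (fraction 0). ``reference`` is the intact line
    ``(name, mean_chiasmata)`` at fraction 1.0. ``significant`` gives the
    configured test's verdict for a pair of line names.

    Stepping from one line to the next-larger deletion loses the FL
    interval between their breakpoints; the bins overlapping that
    interval are implicated when the two lines differ significantly AND
    the larger deletion lies significantly away from the reference.
    """
    fractions = [f for _, f, _ in series]
    if any(b >= a for a, b in zip(fractions, fractions[1:])):
        raise ValueError("series must be ordered by strictly decreasing fraction retained")
    if any(not 0.0 <= f < 1.0 for f in fractions):
        raise ValueError("series fractions must lie in [0, 1)")

    if callable(significant):
        sig = significant
    else:
        mapping = significant

        def sig(a: str, b: str) -> bool:
            return bool(mapping[frozenset((a, b))])

    ref_name, ref_mean = reference
    arm_bins = sorted((b for b in bins if b.arm == arm), key=lambda b: b.fl_low)
    if not arm_bins:
        raise ValueError(f"no bins on arm {arm!r}")

    steps: list[DropStep] = []
    prev_name, prev_fl, prev_mean = ref_name, 1.0, ref_mean
    for name, fl, mean in series:
        lost = tuple(
            b.name for b in arm_bins
            if b.fl_low < prev_fl and b.fl_high > fl
        )
        step_sig = sig(prev_name, name)
        ref_sig = step_sig if prev_name == ref_name else sig(ref_name, name)
        steps.append(DropStep(
            from_line=prev_name, to_line=name, lost_bins=lost,
            delta_mean=mean - prev_mean,
            step_significant=step_sig, vs_reference_significant=ref_sig,
        ))
        prev_name, prev_fl, prev_mean = name, fl, mean

    implicated: list[str] = []
    for step in steps:
        if step.implicated:
            for b in step.lost_bins:
                if b not in implicated:
                    implicated.append(b)
    return DropAttribution(arm=arm, steps=tuple(steps),
                           implicated_bins=tuple(implicated))


def attribute_drops_from_samples(
    series: Sequence[tuple[str, float, float]],
    reference: tuple[str, float],
    samples: Mapping[str, Sequence[float]],
    bins: Sequence[DeletionBin],
    arm: str,
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
) -> DropAttribution:
    """Drop attribution with significance computed from per-cell samples.

    Each step's two lines and each line-vs-reference contrast are tested
    with Mann-Whitney; p-values are Bonferroni-corrected over the family
    of step tests (m defaults to the number of steps) so that a long
    series of null steps does not accumulate false implications.
    """
    from .stats import bonferroni_alpha, mann_whitney

    m = bonferroni_m if bonferroni_m is not None else max(1, len(series))
    threshold = bonferroni_alpha(alpha, m)
    cache: dict[frozenset, bool] = {}

    def significant(a: str, b: str) -> bool:
        key = frozenset((a, b))
        if key not in cache:
            _, p = mann_whitney(samples[a], samples[b])
            cache[key] = p < threshold
        return cache[key]

    return attribute_drops(series, reference, significant, bins, arm)


# ---------------------------------------------------------------------------
# BED-like I/O (arm, start, end, name), coordinate system in a header line


def write_bin_table(bins: Sequence[DeletionBin], path: str | Path,
                    coordinates: str = "fraction") -> None:
    if coordinates not in {"fraction", "mb"}:
        raise ValueError("coordinates must be 'fraction' or 'mb'")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# coordinates={coordinates}\n")
        fh.write("arm\tstart\tend\tname\n")
        for b in bins:
            if coordinates == "fraction":
                fh.write(f"{b.arm}\t{b.fl_low:.2f}\t{b.fl_high:.2f}\t{b.name}\n")
            else:
                if b.phys_low is None or b.phys_high is None:
                    raise ValueError(f"bin {b.name} lacks physical bounds")
                fh.write(f"{b.arm}\t{b.phys_low}\t{b.phys_high}\t{b.name}\n")


def read_bin_table(path: str | Path) -> list[DeletionBin]:
    path = Path(path)
    coordinates = "fraction"
    bins: list[DeletionBin] = []
    with path.open() as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                m = re.search(r"coordinates=(\w+)", line)
                if m:
                    coordinates = m.group(1)
                continue
            if not line.strip():
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != ["arm", "start", "end", "name"]:
                    raise ValueError(f"{path}:{lineno}: bad header {fields}")
                header_seen = True
                continue
            arm, start, end, name = fields
            if coordinates == "fraction":
                bins.append(DeletionBin(name=name, arm=arm,
                                        fl_low=float(start), fl_high=float(end)))
            else:
                lo, hi = float(start), float(end)
                # FL bounds unknown in a pure-Mb table; store a placeholder
                # spanning interval so the object is still well-formed.
                bins.append(DeletionBin(name=name, arm=arm, fl_low=0.0, fl_high=1.0,
                                        phys_low=lo, phys_high=hi))
    if not bins:
        raise ValueError(f"{path}: no bins read")
    return bins
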