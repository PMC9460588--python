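"""Published summary tables for the wheat chromosome-3B aneuploid series.

These are the printed inputs the pipeline consumes when the raw per-cell
scores are not available: per-line mean metaphase-I configurations for
Chinese Spring (CS) and its aneuploid derivatives, the thirteen terminal
deletion lines that define the cytogenetic deletion bins on 3B, per-bin
gene content and expression summaries, and the FPKM values of the
known-meiotic-gene homoeologue triads.

Values are stored exactly as printed (means and standard deviations over
50 pollen mother cells per line for the cytology; FPKM averaged over four
meiotic anther stages and two replicates for the expression data).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "line_summaries",
    "line_karyotypes",
    "deletion_lines",
    "bin_summary_table",
    "meiotic_gene_table",
    "MULTIVALENT_FREE_LINES",
]

# line, % arm present, 2n as printed, declared chromosome units
# (telosomes count one unit each: "40+2t" -> 42, "41+t" -> 42),
# then mean, sd pairs: chiasmata, univalents, bivalents, rods, rings,
# multivalents.
_LINE_ROWS = [
    # line        arm%  2n        units chia        univ        biv          rods         rings        multi
    ("CS",        100, "42",     42, 40.98, 1.12, 0.04, 0.28, 20.98, 0.14,  1.02, 1.12, 19.98, 1.12, 0.00, 0.00),
    ("N3B",         0, "40",     40, 35.22, 1.99, 0.44, 0.84, 19.78, 0.42,  4.34, 1.76, 15.44, 1.83, 0.00, 0.00),
    ("N3AT3B",    100, "42",     42, 38.44, 2.35, 0.04, 0.28, 20.42, 0.91,  2.34, 1.49, 18.08, 1.69, 0.28, 0.45),
    ("N3AT3D",    100, "42",     42, 38.82, 2.09, 0.28, 0.70, 20.22, 0.95,  2.90, 1.93, 17.32, 1.96, 0.32, 0.47),
    ("N3BT3A",      0, "42",     42, 36.74, 1.98, 0.88, 1.14, 19.46, 1.16,  4.34, 1.49, 15.12, 1.75, 0.56, 0.50),
    ("N3BT3D",      0, "42",     42, 37.32, 1.91, 0.52, 0.89, 19.70, 0.91,  4.08, 1.91, 15.62, 2.18, 0.52, 0.50),
    ("N3DT3A",    100, "42",     42, 39.94, 1.56, 0.08, 0.40, 20.28, 1.07,  1.92, 1.56, 18.36, 1.75, 0.34, 0.52),
    ("N3DT3B",    100, "42",     42, 39.82, 1.48, 0.08, 0.40, 20.24, 0.96,  1.98, 1.38, 18.26, 1.58, 0.36, 0.48),
    ("Dt3BL",     100, "40+2t",  42, 39.44, 1.32, 0.08, 0.40, 20.96, 0.20,  2.48, 1.23, 18.48, 1.27, 0.00, 0.00),
    ("Dt3BS",     100, "40+2t",  42, 25.84, 2.94, 6.16, 3.61, 17.92, 1.81, 10.00, 2.11,  7.92, 1.82, 0.00, 0.00),
    ("F1CSx3BS",  100, "41+t",   42, 36.44, 1.89, 2.00, 1.47, 19.84, 0.99,  4.16, 1.77, 15.68, 1.89, 0.44, 0.51),
    ("F1CSx3BL",  100, "41+t",   42, 39.30, 1.09, 0.16, 0.55, 20.92, 0.27,  2.54, 1.11, 18.38, 1.07, 0.00, 0.00),
    ("3BS3",       87, "42",     42, 39.64, 1.32, 0.04, 0.28, 20.98, 0.14,  2.32, 1.33, 18.66, 1.32, 0.00, 0.00),
    ("3BS8",       78, "42",     42, 39.92, 1.63, 0.12, 0.48, 20.94, 0.24,  1.96, 1.58, 18.98, 1.58, 0.00, 0.00),
    ("3BS7",       75, "42",     42, 40.40, 1.21, 0.12, 0.48, 20.94, 0.24,  1.48, 1.16, 19.46, 1.16, 0.00, 0.00),
    ("3BS2",       57, "42",     42, 40.32, 1.20, 0.04, 0.28, 20.98, 0.14,  1.64, 1.16, 19.34, 1.71, 0.00, 0.00),
    ("3BS4",       55, "42",     42, 39.78, 1.53, 0.04, 0.28, 20.98, 0.14,  2.18, 1.48, 18.80, 1.50, 0.00, 0.00),
    ("3BS1",       33, "42",     42, 40.20, 0.97, 0.04, 0.28, 20.98, 0.14,  1.76, 0.96, 19.22, 0.95, 0.00, 0.00),
    ("3BS5",        7, "42",     42, 39.64, 1.50, 0.08, 0.57, 20.96, 0.28,  2.28, 1.34, 18.68, 1.39, 0.00, 0.00),
    ("3BL2",       22, "42",     42, 34.00, 2.48, 2.20, 1.91, 19.90, 0.95,  5.80, 1.84, 14.10, 1.92, 0.00, 0.00),
    ("3BL8",       28, "42",     42, 37.54, 1.84, 0.36, 0.78, 20.82, 0.39,  4.10, 1.69, 16.72, 1.73, 0.00, 0.00),
    ("3BL1",       31, "42",     42, 36.80, 2.16, 1.22, 1.11, 20.20, 0.83,  4.52, 1.95, 15.68, 2.03, 0.46, 0.50),
    ("3BL9",       38, "41",     41, 33.10, 2.38, 2.18, 1.51, 19.38, 0.83,  5.70, 1.82, 13.68, 2.00, 0.02, 0.14),
    ("3BL10",      50, "42",     42, 35.90, 2.50, 1.04, 1.47, 20.44, 0.76,  5.04, 2.02, 15.40, 2.15, 0.02, 0.14),
    ("3BL7",       63, "41",     41, 33.46, 2.57, 2.12, 1.22, 19.44, 0.61,  5.42, 2.13, 14.02, 2.28, 0.00, 0.00),
]

#: Lines whose printed multivalent mean is zero, for which the scoring
#: identity (chiasmata = rods + 2*rings) can be checked on the printed row.
MULTIVALENT_FREE_LINES = (
    "CS", "N3B", "Dt3BL", "Dt3BS", "F1CSx3BL",
    "3BS3", "3BS8", "3BS7", "3BS2", "3BS4", "3BS1", "3BS5",
    "3BL2", "3BL8", "3BL7",
)


def line_summaries() -> pd.DataFrame:
    """Per-line configuration and chiasma means +- SD, 50 cells per line."""
    cols = [
        "line_id", "pct_arm", "two_n", "total_units",
        "chiasmata_mean", "chiasmata_sd", "univalents_mean", "univalents_sd",
        "bivalents_mean", "bivalents_sd", "rods_mean", "rods_sd",
        "rings_mean", "rings_sd", "multivalents_mean", "multivalents_sd",
    ]
    df = pd.DataFrame(_LINE_ROWS, columns=cols)
    df["n_cells"] = 50
    return df


def line_karyotypes() -> pd.DataFrame:
    """Declared chromosome-unit totals per line."""
    df = line_summaries()
    return df[["line_id", "two_n", "total_units"]].copy()


# Thirteen terminal deletion lines, named <arm><serial>-<fraction retained>.
_DELETION_LINES = [
    ("3BS3-0.87", "S", 0.87),
    ("3BS8-0.78", "S", 0.78),
    ("3BS7-0.75", "S", 0.75),
    ("3BS2-0.57", "S", 0.57),
    ("3BS4-0.55", "S", 0.55),
    ("3BS1-0.33", "S", 0.33),
    ("3BS5-0.07", "S", 0.07),
    ("3BL2-0.22", "L", 0.22),
    ("3BL8-0.28", "L", 0.28),
    ("3BL1-0.31", "L", 0.31),
    ("3BL9-0.38", "L", 0.38),
    ("3BL10-0.50", "L", 0.50),
    ("3BL7-0.63", "L", 0.63),
]


def deletion_lines() -> pd.DataFrame:
    """The thirteen deletion-line definitions (name, arm, fraction retained)."""
    return pd.DataFrame(_DELETION_LINES, columns=["name", "arm", "fraction_retained"])


# Per-bin gene content: estimated physical size (Mb), genes mapped,
# genes expressed during meiosis (FPKM > 5), and genes overexpressed on
# the B copy (fold change > 2 vs both A and D). Bin labels as printed in
# the expression summary (the long-arm 3BL8/3BL1 boundary is printed 0.32
# there, vs 0.31 in the deletion-line list; labels are kept verbatim).
_BIN_ROWS = [
    ("S", "3BS3-0.87-1.00",   4.46,   93,  28, 30.11,   7),
    ("S", "3BS8-0.78-0.87",  31.38,  519, 100, 19.27,  23),
    ("S", "3BS7-0.75-0.78",   5.93,   58,  18, 31.03,   3),
    ("S", "3BS2-0.57-0.75",  75.56,  644, 189, 29.35,  38),
    ("S", "3BS4-0.55-0.57",  20.31,  117,  47, 40.17,   8),
    ("S", "3BS1-0.33-0.55", 105.52,  608, 241, 39.64,  43),
    ("S", "3BS5-0.07-0.33",  53.08,  149,  85, 57.05,  12),
    ("S", "C-3BS5-0.07",     48.04,   67,  38, 56.72,  11),
    ("L", "C-3BL2-0.22",     90.60,  416, 223, 53.61,  40),
    ("L", "3BL2-0.22-0.28",  28.46,  189,  67, 35.45,  19),
    ("L", "3BL8-0.28-0.32",  17.85,  106,  48, 45.28,  11),
    ("L", "3BL1-0.32-0.38",  43.64,  260, 124, 47.69,  16),
    ("L", "3BL9-0.38-0.50",  44.96,  359, 164, 45.68,  25),
    ("L", "3BL10-0.50-0.63", 48.48,  314, 144, 45.86,  26),
    ("L", "3BL7-0.63-1.00", 204.93, 2161, 583, 26.98, 115),
]


def bin_summary_table() -> pd.DataFrame:
    """Published per-bin gene counts and expression summary."""
    return pd.DataFrame(
        _BIN_ROWS,
        columns=["arm", "bin", "size_mb", "n_mapped", "n_expressed",
                 "pct_expressed", "n_overexpressed_b"],
    )


# Known meiotic genes assigned to 3B deletion bins with mean FPKM of the
# A/B/D homoeologous copies (None = no copy found). The MLH1 3D value is
# the mean of its two 3D copies.
_GENE_ROWS = [
    ("BRCA2",        "3BS2-0.57-0.75", "TraesCS3B02G115500",  5.26,  1.75,  0.93),
    ("MSH7",         "3BS4-0.55-0.57", "TraesCS3B02G136600",  4.13,  3.08,  3.37),
    ("DUO1-3S",      "3BS1-0.33-0.55", "TraesCS3B02G178200",  0.45,  0.74,  7.37),
    ("CYCA1;2/TAM1", "3BS1-0.33-0.55", "TraesCS3B02G183400",  None, 24.66,  None),
    ("MUS81-3S",     "3BS5-0.07-0.33", "TraesCS3B02G218300",  6.29,  6.41, 21.67),
    ("RTEL1",        "C-3BL2-0.22",    "TraesCS3B02G242700",  5.87,  2.92,  2.29),
    ("DUO1-3L",      "C-3BL2-0.22",    "TraesCS3B02G254800",  4.77,  4.07,  3.30),
    ("MPK4-1",       "C-3BL2-0.22",    "TraesCS3B02G256700", 21.08,  9.83,  7.61),
    ("MPK4-2",       "C-3BL2-0.22",    "TraesCS3B02G260900",  4.07,  4.47,  7.44),
    ("MPK4-3",       "C-3BL2-0.22",    "TraesCS3B02G270200", 13.01, 17.93, 14.06),
    ("ASK1/ASK2",    "3BL1-0.32-0.38", "TraesCS3B02G308600",  None,  None,  None),
    ("CAP-E1/E2",    "3BL7-0.63-1.00", "TraesCS3B02G423800", 11.63, 18.08, 11.23),
    ("SYN4",         "3BL7-0.63-1.00", "TraesCS3B02G429700", 20.58, 16.23, 31.22),
    ("ZIP4",         "3BL7-0.63-1.00", "TraesCS3B02G434600",  5.79,  5.91,  6.07),
    ("MUS81-3L",     "3BL7-0.63-1.00", "TraesCS3B02G535000",  9.96, 19.29, 36.59),
    ("MLH1",         "3BL7-0.63-1.00", "TraesCS3B02G564100",  3.90, 13.29, 12.06),
]

#: Most-expressed copy as printed (bold in the source table); None where
#: fewer than two copies have values.
MOST_EXPRESSED_COPY = {
    "BRCA2": "A", "MSH7": "A", "DUO1-3S": "D", "CYCA1;2/TAM1": None,
    "MUS81-3S": "D", "RTEL1": "A", "DUO1-3L": "A", "MPK4-1": "A",
    "MPK4-2": "D", "MPK4-3": "B", "ASK1/ASK2": None, "CAP-E1/E2": "B",
    "SYN4": "D", "ZIP4": "D", "MUS81-3L": "D", "MLH1": "B",
}


def meiotic_gene_table() -> pd.DataFrame:
    """Known meiotic genes on 3B with homoeologue-triad mean FPKM."""
    return pd.DataFrame(
        _GENE_ROWS,
        columns=["gene", "bin", "gene_id_b", "fpkm_a", "fpkm_b", "fpkm_d"],
    )
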