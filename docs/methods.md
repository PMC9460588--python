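# Methods

## Chiasma scoring and accounting

A pollen mother cell at metaphase I is recorded as counts of
univalents, rod bivalents, ring bivalents, trivalents and
quadrivalents. Scoring weights are (0, 1, 2, 3, 4) chiasmata
respectively: a rod has one bound arm, a ring two, and multivalent
associations are counted by their chain length. Scoring is linear in
the counts, so the mean chiasma count of a line can equivalently be
computed from per-cell scores or from the mean configuration counts;
`summarize_line` scores per cell first and reports sample standard
deviations with the n − 1 denominator (conventional for 50-cell
cytological samples).

Every cell must satisfy `univalents + 2·bivalents + 3·trivalents +
4·quadrivalents = 2n` in chromosome units, with telocentric
chromosomes counting one unit each (so a "40 + 2t" ditelosomic has 42
units). Violations are flagged per cell, not fatal: real scoring sheets
contain occasional miscounts and the analysis should surface rather
than silently drop them. Trivalents and quadrivalents are stored
separately; the pooled "multivalents" column of the classical
presentation is an export option, because pooled counts cannot be
un-mixed afterwards (3- and 4-unit associations contribute differently
to both scoring and accounting).

## Statistical battery

Chiasma counts are small integers with heavy ties, so all comparisons
are rank-based with midranks and tie-corrected variances:

- **Shapiro–Wilk** documents non-normality per sample; constant samples
  return a flagged degenerate result instead of an error.
- **Kruskal–Wallis** (scipy, tie-corrected) is the global k-line test.
- **Mann–Whitney** uses the exact no-tie distribution when both samples
  are below 20 observations, full enumeration of group assignments when
  ties are present and `C(n_a+n_b, n_a) ≤ 200 000`, and otherwise the
  normal approximation with tie-corrected variance and continuity
  correction. Two-sided ("bilateral") by default.
- **Dunn's procedure** computes all-pairs z statistics on the pooled
  ranks, `z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T/(12(N−1)))(1/n_i +
  1/n_j))` with `T = Σ(t³ − t)` over tie groups; the multiplicity
  adjustment (Bonferroni by default, Holm or none configurable) is
  applied within one trait column at a time.
- **Bonferroni** exposes both adjusted p-values `min(1, m·p)` and the
  altered threshold `α/m`; the family size m defaults to the number of
  comparisons actually run but is configurable, since which contrasts
  form "the family" is an analysis decision.

### Compact letter display

Lines are ordered by decreasing trait mean; maximal contiguous runs of
mutually non-significant lines each receive one letter, contained runs
are absorbed, and a line's letters are the union over the runs covering
it. Two lines then share a letter exactly when they do not differ
significantly — provided the non-significance relation is *contiguous*
under the mean ordering. When it is not (x ∼ z but an intermediate y
differs from one of them), no letter display can represent the
relation; the lines involved in a violating triple are flagged NA and
removed, iterating until the remainder is contiguous. An assignment is
marked `representable` only when no line was flagged. This mirrors how
published tables handle non-transitive significance: an explicit NA
rather than a misleading letter.

### cis-adjusted contrast

Terminal deletions remove a segment that would itself carry chiasmata,
so a deletion line can sit significantly below the euploid without any
trans-acting gene being lost. `cis_adjusted_test` shifts the reference
sample down by δ (default 1 chiasma, the expected loss for a distal
segment of one arm) and re-tests; a contrast that is significant
unadjusted but not after the shift is classified as cis. δ is a model
assumption, not an estimate — sensitivity to δ should be reported when
the expected segment loss is uncertain.

## Deletion bins and drop attribution

Deletion lines are named `<arm><serial>-<FL>` with FL the fraction of
the arm retained, to two decimals; parsing round-trips. Sorted
breakpoints of one arm define half-open bins `[fl_low, fl_high)` (the
terminal bin closed at 1.00), each named `<proximal line>-<distal
fraction>`, plus a centromeric `C-<line>` bin. Physical bin sizes in Mb
are *inputs* (from cytogenetic estimates), never interpolated from FL:
fraction length is a cytological measure and is not proportional to
physical distance.

Drop attribution walks a nested series ordered by decreasing fraction
retained, starting at the intact reference and optionally ending at the
line missing the whole arm. The step from one line to the next-larger
deletion loses a known FL interval; the bins overlapping it are
implicated when (a) the two lines differ significantly under the
configured test and (b) the larger deletion is also significantly away
from the reference. This deliberately mirrors the line-vs-line plus
line-vs-reference reasoning used with such series rather than fitting a
changepoint model: with ≤ 8 lines per arm there is little power to
estimate one, and the two-condition rule is robust to the series being
non-monotone in the means. When significance is computed from per-cell
samples (`attribute_drops_from_samples`), the per-step Mann–Whitney
tests are Bonferroni-corrected over the number of steps; without this,
a series with s null steps would falsely implicate some bin with
probability ≈ s·α, making exact recovery of a single planted effect
impossible at the stated rates.

## Expression screen

- **Expressed**: a gene copy is expressed when any per-stage mean FPKM
  (replicates averaged first) strictly exceeds 5. The "condition" is
  the meiotic stage (4 stages × 2 replicates in the reference design);
  averaging replicates first is the natural unit since replicates are
  technical repeats of one stage.
- **B-overexpression**: grand-mean FPKM fold change > 2 against both
  the A and the D homoeologue. Genes lacking an A or D copy count as
  overexpressed (no homoeologue can contradict the call), as do zero
  homoeologue means with non-zero B. A configurable pseudocount
  (default 0) can damp near-zero denominators.
- **Most-expressed copy**: largest grand-mean FPKM among the copies
  present (≥ 2 required); exact ties are reported as ties, never broken
  arbitrarily. Multiple same-subgenome copies are averaged before the
  comparison.
- **Per-bin summary**: mapped / expressed / % expressed (2 decimals,
  half-up) / B-overexpressed per bin, with per-arm and grand totals
  that are exact sums of the bin rows.
- **Alignment-hit filter**: protein-alignment hits are kept only with
  score > 500, identity > 40% and similarity > 60% (all strict),
  preserving input order.
- **Functionality triage** of aligned protein copies assumes the
  diploid progenitors (AA and DD) are functional: positions where the
  two diploid copies disagree are masked as neutral; a polyploid A (D)
  copy deviating from the diploid A (D) at unmasked positions in more
  than a configurable fraction of varieties (default > 50%, "recurrent")
  is flagged doubtful, as is a B copy deviating from the A/D consensus;
  premature stops and gaps at conserved positions always flag. The
  recurrence fraction is a free parameter because "recurrent" has no
  canonical value; calls are a triage, not a functional assay.

## The generator

The generator stands in for raw per-cell scoring sheets. Per normal
pair and cell: the obligate crossover succeeds with probability
`trans_factor·(1 − p_obligate_fail)`; a bound pair adds
`Poisson(lambda_extra·trans_factor)` extra crossovers; 0/1/≥2
crossovers appear as a univalent couple / rod / ring. Scoring saturates
at 2 per bivalent, matching what slides show. Expected chiasmata per
cell has the closed form

    E = n_pairs·s·(2 − exp(−λ·tf)) + n_telo·s,   s = tf·(1 − p_fail)

(adjusted for cis loss and quadrivalents as below), which the simulated
mean converges to; `model_from_line_means` inverts it to moment-match a
scenario to a line's printed chiasma and univalent means (trans effects
are then absorbed into `p_obligate_fail` and `lambda_extra`, which is
what per-line calibration can identify). The euploid scenario lands at
λ ≈ 3.06, p_fail ≈ 0.001 — ~20 rings, ~1 rod, ~0.04 univalents per
cell.

Design choices:

- **Trans effects** scale linearly: success probability and extra-CO
  rate are both multiplied by `trans_factor`, making mean chiasmata
  strictly increasing in it.
- **Cis loss** removes `floor(c) + Bernoulli(frac(c))` chiasmata from
  the deletion-carrier pair after classification capacity (ring → rod →
  univalent couple). A planted c = 1 therefore produces an observed
  per-cell drop of ≈ 1·P(pair bound) ≈ 1, exactly the situation the
  δ = 1 cis adjustment assumes — the carrier bivalent loses one bound
  arm, and when its only crossover sat in the lost segment the pair
  falls apart into univalents. Accounting still holds for every cell.
- **Telosome pairs** (ditelosomics) can at best form a rod; their
  obligate-failure draw uses the same `s`, which reproduces both the
  extra rod and the chiasma deficit of one-armed lines.
- **Quadrivalents** are off by default (euploids show essentially
  none); a per-pair-couple rate exists to exercise the pooled
  multivalent export.
- **Moment fitting** uses univalent frequency for `p_fail` and the rod
  fraction among bound pairs for `λ = −log(rod/(rod+ring))`; all-ring
  data are a flagged boundary (rate capped at 20), all-rod data give
  λ = 0.

The fixture generator for the expression screen plants gene positions
uniformly within bins and log-normal FPKM triads whose expressed /
B-overexpressed flags are exact by construction (counts can be pinned
per bin), with one alignment hit per gene passing the filter exactly
for the expressed subset.

What the generator does **not** emulate: crossover interference and
the spatial placement of chiasmata within arms, inter-cell correlation
from shared anthers or plants, multivalent geometry beyond a simple
rate, scoring error, and any dependence between cytology and
expression. Passing tests therefore demonstrate the pipeline's
correctness and calibration under this model, not biological claims
about real lines.

## Problem sizes and numerical conventions

Simulation-based checks use 50 cells per line (the protocol's sample
size) with 100–150 replicates for recovery rates, 2000 null datasets of
5 × 20 cells for the type-I calibration of the global test, and 10 000
cells for parameter recovery; exhaustive-permutation oracles run at
total n ≤ 10 and the letter-display brute force at ≤ 8 groups. Display
rounding is half-up to 2 decimals and applied only in reports; internal
computation is unrounded. Exact Mann–Whitney enumeration is capped at
200 000 assignments. All randomness flows through a single seedable
`numpy` generator; fixed seed means byte-identical output.

## Known limitations

- Printed summary tables of the classical aneuploid series are embedded
  as reference inputs; their occasional internal inconsistencies (a
  pooled bivalent mean differing from rods + rings by one rounding
  step, pooled multivalent columns that cannot be split) are preserved
  verbatim and surfaced, not corrected.
- Drop attribution assumes a nested terminal-deletion series; it does
  not handle interstitial deletions or radiation-hybrid panels, though
  externally characterized lines can be appended to a series to narrow
  an implicated bin.
- The cis adjustment uses a fixed δ rather than estimating segment-
  specific chiasma content.
- The triage step treats all residue substitutions equally; it does not
  score biochemical severity.
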