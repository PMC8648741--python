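# Methods

## The random breakage model and the Hscore

The null model treats the readable genome — the `L` base pairs that can
carry a mapped breakpoint; 2,948,611,470 bp for ungapped hg38, the summed
chromosome lengths for gapless synthetic genomes — as homogeneous: each
base carries a breakpoint with probability `Pu = n/L`, where `n` is the
total breakpoint count of the set being scored (the whole cohort for
cohort-level questions, one sample's TBPc for per-patient scores). Both
sides of every SV junction count as independent breakpoints.

For one element class, overlapping or bookended intervals are merged
(bedtools semantics) into a track of cumulative length `Li`; `ni` is the
number of breakpoints inside the merged intervals under the half-open
membership test `start <= pos < end`. The hotspotness score is

    Hscore = -log10 P(X > ni),   X ~ Binomial(Li, Pu)

with a strict inequality. The tail is evaluated through scipy's
regularized-incomplete-beta survival function; once it approaches the
double-precision floor (p < 1e-250) the tail is re-summed in log space
from the binomial log-pmf, which keeps the score finite and accurate up
to ~323 (the subnormal limit). A tail that underflows to exactly zero is
reported as an explicit infinity; exports replace it with a configurable
cap (default 350), chosen just above the largest finite representable
score so capped and finite values cannot collide in real data.

Monotonicity (non-decreasing in `ni`, non-increasing in `Li`), exactness
against direct pmf summation on small problems (|Δ| ≤ 1e-9 log10 units),
and conservativeness of the null calibration are exercised in the test
suite. Note the null simulation is slightly under-dispersed relative to
the model (a fixed number of breakpoints is thrown, so in-track counts
are binomial in `n` rather than in `Li`), which makes the calibration
check conservative by construction.

## Windows, hotspots and hot regions

Each element is shifted by k×100 % of its own length, k = −8…+8
(positive = rightward; tracks carry no strand). Shifted intervals are
clipped at chromosome bounds — `Li` at each offset reflects the countable
territory — and intervals pushed entirely off-chromosome are dropped with
a logged count. Each offset-track is merged independently; no exclusion
against the offset-0 elements is applied. The classification uses offsets
0, −1, +1:

* centre ≥ 3, both flanks < 3 → **hotspot**;
* centre ≥ 3, both flanks ≥ 3 → **hotspot** if centre ≥ 1.5×max(flanks),
  else **hot region**;
* centre < 3 → not significant.

The configuration with exactly one significant flank is not covered by
the two rules above; it is resolved by the same 1.5× margin against the
larger flank (hotspot if cleared, otherwise not significant — a hot
region requires both surroundings hot) and flagged `mixed_flanks` in the
output. When centre and both flanks all saturate to infinity the ratio is
indeterminate and the call is the conservative hot region.

## Gene context

An element is *inside* genes when it overlaps any merged TSS–TES interval
by ≥ 1 bp (optionally restricted to genes with expression evidence);
elements are assigned wholly, never split, so element counts are
conserved. Both sub-tracks are scored under the full-set `Pu` — one null,
two territories — and compared as `RHscore i/o = H_in / H_out`. A zero
denominator raises; infinite numerator → inf, infinite denominator → 0,
both infinite → NaN.

## Instability indexes

iTRAC pools RLFS, GQ, CpGi, CRM, SCS-S and all four DHS sub-classes
(`trace_definition(include_dhs_rest=False)` drops the sub-class without
attributable regulatory function); iRACIN pools DR, STR, MR, IR, Z, SR,
MS, LC. SCS-G, LTR, RT and APR belong to neither. Each index is one
merged territory; a patient's value is the Hscore of that territory for
the patient's own breakpoints with the patient's own `Pu` (raw p, no
multiplicity correction — one test per patient per index). Holm
step-down (statsmodels) is reserved for the per-patient × per-class
matrix, with the family = all element classes within one sample. The
published heatmap's rescaling of two extreme samples is available only as
an export option and never touches stored results.

## iPART

Candidate thresholds are the midpoints between consecutive distinct index
values — the finite set of label-distinct cuts. A k-group partition is a
combination of k−1 candidates; every combination whose groups all reach
`min_group_size` (default 5; Kaplan–Meier estimates on smaller groups are
degenerate) is scored by the k-group log-rank statistic, and the largest
statistic wins. Ties break toward the more balanced partition, then
smaller thresholds. Group labels are a monotone step function of the
value (`value <= threshold` → lower group); for k = 3 they are
Low/Medium/High. The single-threshold scan's local minima (plateaus
counted once at their midpoint, boundaries qualifying against one
neighbour) below a cap — 0.10 for iTRAC, 0.3 for iRACIN in the published
analysis — provide the reduced candidate sets for k > 3 searches.

The log-rank machinery is implemented in numpy: partitions by thresholds
are contiguous ranges of the value-sorted cohort, so group at-risk and
death tables for whole batches of threshold combinations come from
cumulative-sum differences, and the (k−1)-df chi-square with the
hypergeometric covariance is evaluated a few thousand combinations at a
time. This is what makes the exhaustive double-threshold search (~2×10⁴
partitions per cohort) and leave-one-out cross-validation (×200 folds)
run in seconds; the statistic agrees with lifelines'
`multivariate_logrank_test` to machine precision (tested).

Two caveats are deliberate. First, the minimized p is optimistically
biased by the search; it is reported as a ranking criterion, and
`permutation_pvalue` (survival permuted against the index, search re-run)
gives an honest level when needed. Second, no automatic winner is
declared across k; `multi_k_report` lists p and the maximal hazard ratio
for k = 2…k_max and leaves the choice to the analyst.

Hazard ratios per group (vs the first group as reference) come from
lifelines Cox proportional-hazards fits on group indicators; a group with
zero events is flagged with an infinite confidence interval rather than
fitted. LOOCV removes one patient, re-runs the full search on the rest,
and labels the held-out patient by the refit thresholds; the output is
the n held-out labels plus the log-rank p of that labelling. The
procedure is exhaustive and deterministic — randomness exists only in the
simulation and permutation utilities.

## MAGIC and treatment stratification

MAGIC calls a patient High-risk exactly when either index's three-group
label is Medium — the Λ-shape finding that intermediate instability
carries the worst prognosis — and Low-risk otherwise. It depends only on
the two labels; samples missing either are excluded with a logged count.
Treatment contrasts fit treated-vs-untreated Cox models within each
group; samples with unannotated treatment are excluded, and strata with
fewer than two patients per arm or zero events are flagged without an
estimate.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:

* **TBPc**: log-normal with meanlog = log 181 and sdlog = 0.64 — the
  pair that reproduces the published cohort's median (181) and mean
  (~222) — clipped to [26, 1200] and rounded up to even so each sample
  holds whole SVs.
* **Positions**: piecewise-constant density — the uniform baseline times
  each class's enrichment factor inside its merged territory,
  renormalized; overlapping territories multiply. Factor 1 everywhere is
  exactly the RBM; factor 0 empties a territory. The default per-class
  factors are qualitative (hotspot classes between 2 and 8, classes the
  cohort analysis found compatible with random breakage at 1).
* **SV pairing**: consecutive draws are paired; each SV is
  intra-chromosomal with probability 0.674 (the published fraction), the
  partner drawn from the density restricted to (or excluding) the first
  side's chromosome. One-chromosome genomes force intra.
* **Placement**: per-class elements never overlap — starts are order
  statistics of the free space — so a class's merged length equals its
  summed element lengths and requested masses beyond a chromosome raise.
* **Survival**: exponential event times per group, hazards
  Low/Medium/High = 0.05/0.5/0.05 per year (the Λ shape), a random
  censoring fraction (default 0.2) censored uniformly before the event,
  and an administrative cap at 30 years. Realized censoring therefore
  exceeds the rate parameter in slow-hazard groups.
* **Defaults**: 10 chromosomes × 10 Mb, 112 samples — desk-scale sizes
  that keep every simulation-backed test in seconds while leaving
  per-track expected counts (~tens) in the regime where the binomial tail
  is informative.

What the generator does **not** emulate: assembly gaps and mappability
holes (so no clipping decisions against gaps arise), chromatin- or
replication-timing-correlated breakage beyond the annotated territories,
SV mechanism (microhomology, templated insertions), dependence between
TBPc and spatial law, and inter-patient sharing of recurrent breakpoints.
Passing tests therefore demonstrate the statistics and the search behave
correctly under their own model assumptions — not that real tumour
genomes satisfy those assumptions.

## Numerical and design notes

* Coordinates are BED (0-based, half-open) everywhere; breakpoints are
  single positions; duplicates at one position all count.
* Interval merge fuses bookended intervals (as bedtools does); covered
  bases, hence `Li` and `ni`, are unaffected by that convention.
* The planted-threshold recovery settings (200 patients, values uniform
  on (0, 3), true thresholds (1.0, 2.0), 10× Medium hazard) recover both
  thresholds within ±0.15 in ≈96 % of cohorts; the hot-region
  discrimination check plants factor 10 over elements ± 3 widths with
  1,000 breakpoints, where all three windows clear Hscore 3 with > 3σ to
  spare (at factor 5 and 300 breakpoints the three-way significance
  requirement hovers near its pass mark by design noise).
* Known limitation: the asymptotic chi-square p of the log-rank test
  carries a small-sample error of order 0.01 absolute at n ≈ 40 in the
  lower tail (the exact permutation p is slightly larger). This is a
  property of the standard test — lifelines produces the identical
  statistic — so permutation calibration checks are meaningful only where
  that error is below Monte-Carlo resolution, i.e. at moderate p; for
  sharp small-sample inference use `permutation_logrank_p`.
* CLI tables print floats at 6 significant digits, making re-runs on
  identical inputs byte-identical; every output directory carries a
  manifest (command, config, seed, input checksums, version, timestamp).
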