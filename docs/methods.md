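# Methods

## Estimand and regression model

The screen measures *relative* chronological lifespan: the trend of a
strain's frequency among alive cells in a starving pool. Absolute survival
curves are out of scope — a strain dying exactly at the pool-average rate has
a flat frequency trajectory and a slope of zero.

Per sample, frequencies are `p = count / sample total`. Because binomial
proportions have frequency-dependent variance, `p` is transformed with the
angular (arcsine square-root) transform before regression. The transform is
expressed in **degrees** so that slopes carry units of degrees/day and the
0/45/90° anchors hold at p = 0, 0.5, 1. Zero counts map to exactly 0° with no
pseudocount by default — the transform is defined there and nothing in the
measurement model demands a correction; `compute_frequencies(...,
anscombe=True)` switches to the Anscombe proportion `(x + 3/8)/(n + 3/4)` for
sensitivity analysis.

Slopes are ordinary least squares of θ against days, fitted **per replicate
series** and then averaged (four slopes per environment; the combined slope
averages all eight). Averaging replicate-level fits rather than pooling all
points into one regression keeps flask-to-flask variation visible and makes
each replicate an exchangeable unit. Intercepts are retained for plotting but
play no role in classification. A replicate series with fewer than two finite
points is dropped from the means with a logged note rather than erroring: one
failed sample should not void a strain.

## Inclusion filter and overlap

A strain is analysable in an environment only if its reads, summed over the
four replicates and all sampled timepoints of that environment, reach 160;
totals strictly below are discarded. The per-environment total is the only
reading under which one number exists per strain-environment pair. Whether
the day-0 sample enters the total is configurable (`call_amplified(...,
timepoints=...)`); the default includes every sampled timepoint. A strain may
pass in one environment only; dual-environment operations (classification,
overlap) intersect the per-environment pass flags.

The overlap of the H- and G-passing sets is reported against the
hypergeometric mean `nH * nG / N` — the expected overlap of independent draws
of those sizes from the assayed pool. No significance test is attached: the
comparison of observed and expected is descriptive, and at screen scale the
departure is orders of magnitude beyond any sensible null.

## L/M/S classification

L requires a positive average slope in both environments — a sign criterion,
deliberately parameter-free. S takes the `n_S` most negative combined slopes
*among strains negative in both environments* (double-negativity is an
eligibility gate, not a ranking tie-break), and M the `n_M` smallest
|combined slope| among what remains. `n_S` and `n_M` default to 66 and 13,
the realized cohort sizes after assay-suitability exclusions in the screen
this package models; they are exposed as parameters because the original
selection preceded exclusions that are not reconstructable from counts alone.
Requesting more members than candidates is an error, not a truncation.

## Minimum-hypergeometric enrichment

Rankings order filter-passing strains by average slope in one environment,
best- or worst-first, with lexicographic tie-breaks so the order is a
deterministic total order (the statistic is order-sensitive; determinism
beats unstated intent). For a term occupying B of N ranked ids, the mHG
statistic is `min over prefixes n in 1..N-1` of the hypergeometric upper tail
`P(X >= b_n)`. The minimum over dependent prefixes is not itself a p-value;
the exact p-value is the permutation probability that the minimum reaches the
observed value, computed by the standard O(N·B) dynamic program: propagate
the hypergeometric-walk probability over (prefix length, members seen)
states, zeroing states whose tail already reaches the observed statistic,
and subtract the surviving mass from one. The DP and the brute-force
enumeration oracle share one precomputed tail table so float ties resolve
identically; their agreement is verified exhaustively for all N ≤ 12, B ≤ 4
(worst relative deviation ~1e-13). Benjamini–Hochberg is applied across
tested terms; terms with zero or all members in the ranking carry no signal
and are skipped with a note. No GO-graph ancestor propagation is performed —
the annotation file is taken as given.

## Synthetic screen generator

The generator emulates the experimental design, not its chemistry: eight
flasks (2 environments × 4 replicates), ~6000 cells per strain at day 0,
weekly sampling from day 0 to 28 (a `drop_day0()` variant supports analyses
that exclude the day-0 sample, since the design is describable both ways).

- **Survival** is exponential per strain: alive cells ∝ `exp(-d_i t)`. The
  screen itself asserts no survival law; exponential decay is the simplest
  monotone model whose transformed-frequency trend is approximately linear,
  matching the regression estimand. Baseline rates are log-normal (default
  median 0.05/day, i.e. ~25% survival at day 28, sdlog 0.5), with a small
  additive per-environment perturbation (default SD 0.005/day).
- **Plating bottleneck**: each sample draws a fixed number of cells
  (default 200 000) multinomially from the alive pool — sampling noise from
  the 0.5-ml aliquot. Plating outgrowth is treated as unbiased, so
  compositions are frequencies among alive cells.
- **Amplification dropout** is a strain-by-environment efficiency weight
  from a two-component Beta mixture (well ≈ 0.9, poor ≈ 0.005; well fraction
  0.12, matching the ~800/6712 well-amplified fraction at screen scale). A
  correlation knob (default 0.95) is the probability a strain keeps its
  component across environments, producing the observed repeatable dropout
  with a single mechanism; hard exclusion is a special case (poor efficiency
  0). Efficiency is constant over time — dropout is strain-intrinsic, which
  is exactly the property the overlap statistic detects.
- **Sequencing** draws `read_depth` reads multinomially with weights
  (plated cells × efficiency); counts per sample sum exactly to the depth,
  and identical configs and seeds give byte-identical tensors.

Not emulated: sequence-level artifacts (PCR-cycle chemistry, read mapping),
growth-phase competition before starvation, plating outgrowth bias, and any
time-varying amplification. Passing recovery tests therefore show that the
inference chain is correct under the stated generative model, not that real
screens are free of those effects.

## Phenotype assays

ATP is luminescence divided by cell count. The ROS score is the median stain
fluorescence of net-positive events divided by the mean cell size of the
strain's gated events; "net-positive" means above a configurable quantile
(default 0.99) of the unstained, size-matched control — "signals equal to
unstained cells" defines no operational cutoff, so a high quantile of the
control distribution stands in for it. If nothing clears the cutoff the score
is missing (no net signal), not an error. Dead fraction is the share of gated
events above a viability-dye cutoff. Gating arrives as boolean event flags;
instrument gating geometry is out of scope. Group comparisons (L vs M vs S)
use strain-level replicate-averaged values as units — three independently
prepared samples per strain are averaged first — with a two-sided
Mann-Whitney U by default (the underlying test behind the original pairwise
comparisons is not stated; a rank-based default is robust and the choice is
surfaced in the API).

## Transcriptome concordance

Counts are library-size normalized to CPM; per-gene log₂ fold changes of each
test strain against the common control use replicate-mean CPM with a 0.5
pseudocount. Concordance between the two fold-change vectors is reported as
Pearson and Spearman correlation over genes finite in both, plus overlap and
Jaccard of the fourfold (|log₂FC| ≥ 2) and sixteenfold (|log₂FC| ≥ 4) flag
sets, both thresholds configurable. Negative-binomial differential-expression
testing is deliberately not reimplemented — the displayed quantities are fold
changes and their correlation, which this module defines end to end.

## Problem sizes and numerical choices

The recovery experiments simulate 500 strains at depths 10⁴–10⁶ with the
full 2 × 4 × 5 design and a fully well-amplified pool — slope recovery is the
quantity under test there, while dropout realism is exercised separately by
the overlap properties; at these sizes the whole acceptance run takes
seconds. mHG DP-vs-enumeration checks cover all universes with N ≤ 12 and
B ≤ 4 exhaustively; null calibration uses 1000 random rankings at N = 200,
B = 20. OLS slopes are computed by the closed form Σ(t−t̄)(θ−θ̄)/Σ(t−t̄)²,
vectorized over all series with per-series NaN masking; degenerate series
(fewer than two finite points, or no time spread) yield missing slopes.
Ranking ties break lexicographically; classification rank ties resolve by
stable sort order.

## Known limitations

Relative slopes only — no absolute viability; compositional coupling (one
strain's rise is everyone else's fall) is inherent to pooled designs and not
corrected; the exponential-survival and constant-efficiency assumptions of
the simulator are conveniences, not findings; cytometry spectral
compensation, automated gating and FCS parsing are out of scope (event
tables arrive as TSV).
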