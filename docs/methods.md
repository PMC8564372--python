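# Methods

## Overview

The package implements three linked analyses of RA-perturbation
recovery time courses — ternary dynamic-pattern discretization, the
COMPACT comparative pattern-count matrix, and a principal-curve
robustness score — together with a synthetic-data generator that
emulates the study design well enough to give every stage a ground
truth. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic benchmark does and does not
demonstrate.

## Synthetic study generator

One sample per clutch x treatment x time; 12 clutches (A–L), treatments
Control / RA / DEAB, times 0, 1.5, 3, 4.5 h post-washout; clutches A–F
are labelled as an RNA-seq-like assay and G–L as a qPCR-like assay.
Per gene, log2 expression is

```
value(t) = baseline + drift·t/t_max + δ(class, treatment) · A(clutch, treatment) · 2^(−t/h) + ε
```

- **Response classes** δ ∈ {−1, 0, +1}: `null`, `RA_only_up/down`,
  `DEAB_only_up/down`, `both_same` (random shared sign),
  `both_opposite` (up under RA, down under DEAB). Default proportions
  put 55 % of genes in `null`. The 16 RA-network and 6 hox panel genes
  are always `both_opposite` with a shared +2.5 log2 developmental ramp,
  which is what gives the trajectory stage its backbone.
- **Clutch gains and trade-off.** Each clutch has a trade-off
  coordinate u (evenly spaced on [0, 1] by default) and gains
  `A_RA = g·(0.6 + 0.8u)`, `A_DEAB = g·(0.6 + 0.8(1−u))` with
  `gain_scale` g = 2.0 log2 units, so the two gains are perfectly
  anti-correlated across clutches (the Pareto trade-off) and deflections
  at t = 0 span 1.2–2.8 log2 units.
- **Recovery kinetics.** The deflection decays exponentially with a
  clutch half-time (default 1.5 h for all clutches; per-clutch values
  accepted). The exponential form is a modeling choice made for
  analytic tractability — the emulated phenomenon is only that
  treatment/control distances shrink over the course. The planted
  robustness rank of a clutch is the rank of its integrated deviation
  `A · Σ_t 2^(−t/h)`.
- **Noise and baselines.** i.i.d. Gaussian noise, `noise_sd` = 0.3 log2
  units — a mid-range value for bulk biological replicates; the source
  study publishes no noise estimate, so this default is documented
  configuration, not a claim about the study. Baselines are Gaussian in
  log2 (mean 8, sd 2), i.e. log-normal expression; a bounded-uniform
  baseline would create an artificial floor whose rank pile-up distorts
  quantile normalization. Panel genes draw baselines from the
  well-expressed range (mean 9.5, sd 1): these genes were quantifiable
  by qPCR under every condition in the emulated design, so even a full
  down-deflection must stay above the detection floor. Per-gene drift
  slopes are uniform in ±`drift_amplitude` (default 1 log2 over the
  course) and treatment-independent, so drift cancels from every
  treatment-vs-control comparison.
- **qPCR readout.** Ct = 24 − log2 expression plus a pre-amplification
  group offset and technical jitter (sd 0.1 cycles each); three groups
  (L homeolog, S homeolog, both primers) x three replicates. The
  housekeeping gene (gapdh) is an idealized stable reference: constant
  level, no biological noise, so its Ct is identical across treatments
  up to jitter. A noisy reference would inject a coherent per-sample
  offset into every ΔCt — real studies choose reference genes precisely
  to avoid that.
- **RNG.** One root seed; gene assignment, expression noise and Ct
  jitter run on separate child streams (`SeedSequence.spawn`), so equal
  configs give bit-identical data.

What the generator does **not** model: read-level sampling,
library-size variation, count overdispersion, homeolog duplication,
batch effects beyond the assay split. Passing tests therefore show the
pipeline's internal correctness and its behaviour under Gaussian
log-scale noise, not performance on raw sequencing artifacts.

## Preprocessing

- **Minimum-expression filter** (counts scale, threshold 5): a gene is
  removed only if it is below threshold in *every* sample — the
  "minimum expression across all samples" reading; configurable.
- **log2(x + 1)** stands in for a variance-stabilizing transform;
  regularized-log and batch regression are out of scope, and the batch
  structure of the two assays is neutralized by per-assay Z-scoring
  before combination instead.
- **Quantile normalization** equalizes every sample to the mean
  order-statistic distribution; tied values receive the mean of the
  order-statistic means their tie block spans (computed from min/max
  ranks and cumulative sums). With ties the post-hoc "identical sorted
  vectors" invariant holds only up to tie blocks; ranks are always
  preserved. Note a genuine limitation inherited from the method:
  values far in a distribution's tail (e.g. strongly down-regulated
  genes near the detection floor) are magnitude-compressed by rank
  mapping, monotonically but not linearly.
- **Z-scoring** is gene-wise with the n−1 standard deviation, applied
  per assay. Constant genes are dropped with a warning rather than
  zero-filled, to avoid fabricating flat patterns.
- **ΔΔCt**: per gene x sample, Ct is the median over pre-amplification
  groups of the per-group technical median (the median over the three
  primer pools suppresses homeolog-specific amplification); ΔCt
  subtracts the housekeeping Ct; ΔΔCt subtracts the same clutch's
  Control/0 h reference; reported log2 expression is −ΔΔCt.
- **Significance gate**: per-gene two-way fixed-effects ANOVA with
  factors time and treatment plus interaction; the minimum of the three
  effect p-values per gene is Benjamini–Hochberg adjusted across genes
  and thresholded at q ≤ 0.05. Because all genes share one sample
  design, residual sums of squares for the nested model sequence are
  computed with precomputed SVD-based projectors (partial, type-II sums
  of squares; identical to the classical decomposition on balanced
  designs) — a unit test pins the p-values to statsmodels' `anova_lm`.
  This plain ANOVA replaces empirical-Bayes moderation deliberately:
  the gate only selects genes for the pattern stage, and with six
  replicates per cell the moderated and unmoderated tests agree closely
  for all but borderline genes.

## Patterns and COMPACT

Discretization thresholds are linear fold changes applied on the log2
scale: ±2-fold for the t0-referenced analysis (T = 3 non-zero time
points, 27 patterns), ±1.3-fold for the control-referenced COMPACT
analysis (T = 4, 81 patterns). Boundary values count as regulation
(|d| = τ → ±1). Clutch averaging precedes discretization. Pattern
indices are base-3 integers with the earliest time point most
significant (−1→0, 0→1, +1→2).

The t0 analysis runs on genes passing the all-treatment gate; the
COMPACT runs on the union of the per-treatment (Control + one
perturbation) significant sets, with the non-significant side kept at
the all-zero pattern. Coarse-graining pools patterns by the time and
direction of the first non-zero call (1 + 4x2 = 9 groups); a pattern's
"direction" for quadrant classification is likewise the sign of its
first non-zero call, consistent with the onset grouping, and genes with
mixed-sign patterns are flagged in the category table. Treatment
overlap fractions count only genes with a non-zero pattern in a group
as that group's responders.

## Trajectory and robustness score

PCA is computed on the combined, per-assay Z-scored 144-sample matrix
restricted to a gene panel; genes are centered but not rescaled, and
each component's sign is fixed so its largest-magnitude loading is
positive. The principal curve is fitted by iterated
projection/smoothing:

1. initialize λ by projecting samples on the oriented line through the
   0 h-Control centroid (start a) and the centroid of the remaining
   132 samples (start b);
2. smooth each PC coordinate as a least-squares cubic regression spline
   in λ (`smoother_df` basis functions, default 5, interior knots at λ
   quantiles);
3. extend both ends of the smoothed polyline by 2x the terminal
   segment (the classical endpoint stretch — without it, samples beyond
   the data's λ range bunch at the end vertices and the largest
   deviations are clipped);
4. re-orient so the end nearer start a is λ = 0, project all samples
   onto the polyline, and re-anchor λ = 0 at the smallest sample
   projection so max(λ) is the sample span;
5. stop when the relative change in total squared residual is < 1e−4
   (or 50 iterations, or the residual stops decreasing); the
   best-residual iterate is returned with a convergence flag.

Projection onto the polyline is exact per segment, with ties broken
toward smaller λ. Collinear data is a fixed point of this scheme
(residual 0, λ = Euclidean distance from the start-side sample), which
the tests verify to 1e−8, and projections match a brute-force nearest
point search to 1e−6.

The shift `s = Σ_t |λ_treat(t) − λ_ctrl(t)| / max(λ)` uses the maximum
λ over **all** samples on that panel's curve (a per-clutch alternative
is available); per cell the λ mean is used if replicates exist.
Clutches are ranked ascending in s with ties broken by clutch id.
Efficiency/efficacy quadrants cut at the across-clutch median of each
axis per treatment, boundary-inclusive on the low side; the axes'
labels read: low hox shift = effective regulation (outcome protected),
low network shift = efficient regulation (little feedback effort).
Degenerate (zero-spread) axes assign everything to the low bin with a
warning.

Because |Δλ| folds noise, s has a positive bias of order
σ_λ·√(2/π)·T/max(λ) for truly robust clutches; rankings remain
informative because the bias is shared, but absolute s values between
studies with different noise should not be compared.

## Problem sizes and numerical checks

The test suite and the acceptance script use 300–2,000 genes, 12
clutches and 20–24 simulation seeds; these sizes give stable recovery
statistics (noise-free closure is exact; at the default noise the mean
quadrant-b recall is ≈ 1.0 and mean rank correlation ≈ 0.92 per
treatment) while keeping a full run in tens of seconds. Exact
invariants (count conservation, marginal consistency, encode/decode
bijections) are asserted with zero tolerance; floating-point oracles at
1e−6 – 1e−9 as noted above.

## Known limitations

- The smoother behind the study's original curve fit is not published;
  regression splines with df = 5 are a documented stand-in, so λ values
  are comparable in structure but not numerically to the original
  figures.
- One sample per clutch x treatment x time leaves no within-cell
  replication for s; the ranking has no error bars (bootstrap over
  genes would be a natural extension).
- Quantile normalization's tail compression (above) means very large
  down-regulations are under-weighted in λ; this mirrors the method,
  not a bug.
- The ANOVA gate assumes homoscedastic Gaussian residuals per gene; on
  raw counts it should be applied only after a variance-stabilizing
  transform.
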