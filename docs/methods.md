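# Methods

This note documents the model and procedure implemented in `metakin`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open.

## Data model and alignment

The unit of observation is one subject's sampled concentration
trajectory for one metabolite during a graded cycle-ergometry test:
a rest sample, one sample 2:30 min into each 3-minute workload level
(50 W, 75 W, … up to the individual maximum between 150 W and 425 W),
and a recovery sample 5 min after the last level.  Trajectories of
different subjects differ in length, so they are aligned on a relative
workload axis: rest ↦ 0, level at workload W ↦ 100·W/W_max, recovery ↦
a common recovery position.

* **Recovery position** (default 117%). The timestamp-based estimate is
  the cohort median of 100·t_recovery/t_max, where t_max is the
  timestamp of the maximum-load sample.  Under the protocol this ratio
  is (3K+5)/(3K−0.5)·100 for a subject with K levels, and its median
  over the observed workload range lands at ≈118%; the default of 117%
  is the value measured in the reference cohort and is used unless
  `recovery_position="auto"` requests the timestamp estimate.  The two
  differ by well under one grid unit per curve segment and do not change
  any downstream call.
* **Position mapping** is workload-proportional, not index-proportional.
  The two coincide under the uniform 25 W / 3 min protocol except for
  the skipped 25 W step; workload proportionality is what the clustered
  axis ("relative workload") denotes.
* **Interpolation** is piecewise linear onto a grid of step 1 (118
  points from 0 to 117, always containing 0, 100 and the recovery
  position exactly).  Missing samples are dropped with their positions,
  so interior gaps — the documented missing maximum-load samples — are
  bridged by a single linear segment.  There is no extrapolation: a
  subject contributes nothing outside the span of its observed samples.
* **Median curves**: the cohort curve per metabolite is the pointwise
  median over subjects (mean of the central pair for even counts).  The
  median is the pipeline's only outlier defence besides a fixed manual
  exclusion list (`STUDY_EXCLUSIONS`), applied by blanking cells, never
  dropping rows.

## Effect size and testing

The **maximum fold change** orients the ratio of the median curve's
extremes by order of occurrence: MFC = c_max/c_min ≥ 1 when the minimum
comes first, c_min/c_max ≤ 1 otherwise; coincident extrema give exactly
1.  Extremal ties resolve to the earliest index (only relevant for
pathological flat curves).

Per-subject interpolated concentrations at the two extremal grid
positions form the paired sample for a two-sided **Wilcoxon signed-rank
test**.  Zero differences are dropped (the classic treatment; Pratt's
variant is not offered), remaining ties are mid-ranked.  The exact null
distribution is used for n ≤ 25 without ties in |d|, otherwise the
normal approximation with continuity correction; the branch taken is
reported per metabolite, because rank ties at large n make several
metabolites share identical P-values.  Subjects whose observed support
misses either extremal position are excluded and counted; fewer than 6
usable pairs skips the test.  P-values are Benjamini–Hochberg adjusted
across the panel, and classification uses the adjusted values.

A Shapiro–Wilk screen (α = 0.01) at both extrema is computed for the
report only; the pipeline always proceeds nonparametrically so that
P-values are comparable across metabolites.

**Predictor classes** apply the volcano thresholds to the effective
magnitude max(MFC, 1/MFC): moderate above 1.20, strong above 1.40, both
at adjusted P < 0.001.  Using the magnitude treats decreasing
metabolites symmetrically — a deliberate generalisation, since the
reference analysis drew its thresholds only on the increasing side.

## Kinetic signatures

Median curves are smoothed by ordinary least squares with a polynomial
of degree 9 (configurable; the degree trades smoothness against shape
fidelity, and 9 resolves every basis shape on the default grid while
keeping ringing at the few-percent level).  The abscissa is linearly
mapped to [0, 1] before fitting — a raw degree-9 Vandermonde on 0…117
has a condition number far beyond double precision — and coefficients
are reported on that normalised axis.  Signatures are expressed as
relative concentration change 100·(f(s) − f(0))/f(0), which is scale
invariant and exactly 0 at rest.  Residual ringing of a few percent is
reported (via the residual sum of squares), not corrected.

### Response-pattern classification

Five patterns describe a signature: sustained, early, halving, late,
delayed.  A curve whose total range is below 20 percentage points is
**sustained** (±10% around rest is accepted as biological/analytical
variability).  Otherwise the call is made from where the change
accumulates, evaluated at the segment boundaries 25 / 75 / 100
(config-exposed):

1. |rel(recovery) − rel(100)| > |rel(100) − rel(0)| → **delayed**;
2. largest excursion before position 25 ≥ 40% of the total range →
   **early** (also catches an early transient trough that recovers);
3. ≥ 85% of the exercise change reached by position 75 → **halving**;
4. otherwise → **late**.

An earlier design scored the four segments by mean absolute slope and
took the argmax with ties toward the later segment.  That rule is
formally appealing but fragile in practice: the three exercise segments
of a uniform-slope curve tie exactly, and the fitted polynomial's
ringing plus the corner smoothing at the end-of-exercise plateau bias
the late segment low, so noise flips uniform ramps to "halving".  The
cumulative-change rule reproduces the same calls on all ideal shapes
(a uniform ramp reaches exactly 25%/75% at the boundaries and is
therefore late, the tie-toward-later convention) and is stable under
realistic noise.  The fraction thresholds were fixed from the ideal
shapes: a logarithmic early response reaches ~59% of its change by
position 25 and a trough-type early response ~45% of its range, versus
25% for a ramp (hence 0.4); a sigmoid reaches ~96% by position 75
versus 75% for a ramp (hence 0.85).

`match_template` additionally offers a direct least-squares amplitude
fit of each basis shape; a non-constant shape must reduce the residual
norm by more than 5% relative to the anchored-constant fit, because any
shape strictly reduces the residual of pure noise by a little, and
without the margin a flat-plus-noise curve would never resolve to the
constant shape.

## Clustering and shape templates

Signatures are compared by Euclidean distance between **relative**
curves.  Clustering absolute concentrations would let a mM-scale
analyte (glucose) dominate every distance, contradicting both the
observed co-clustering of glucose with a µM-scale acylcarnitine and a
cut height of 35, which is only plausible in percent units; absolute
and row-scaled modes remain available for sensitivity analysis.
Linkage is complete (the common default of the environment the original
analysis ran in) with lowest-index tie-breaking; the tree is cut at
height 35 and cluster ids are numbered by first appearance in
dendrogram leaf order, which makes assignments deterministic and
order-invariant up to renaming.  Each cluster's pointwise median
relative curve is its shape template, labelled by the pattern
classifier.  The row-scaled heatmap export (per-metabolite mean 0 / sd
1, dendrogram leaf order) is display-only and never feeds back into
clustering.

The number of clusters at the default cut is sensitive to the unstated
metric/linkage/curve-scale choices and to noise: with the defaults and
the synthetic study panel at 10% noise the pipeline typically finds
10–12 clusters where the reference cohort showed 7, because ~17
near-flat signatures wiggle independently and complete linkage bounds
cluster diameter.  This quantity should be read as descriptive, not as
a reproduction target.

## Synthetic cohorts

The generator emulates the study conditions: 47 subjects, maximum
workloads uniform over the 25 W steps in 150–425 W (sample counts 7–18
per subject), protocol timestamps (metabolite samples 2:30 min into a
level, lactate 1:30, recovery +5 min), per-metabolite ground-truth
kinetics from seven basis shapes expressed directly on the relative
axis [0, 117] so truth is exactly comparable to pipeline output.  All
exercise-driven shapes are anchored at 0 at rest, reach their amplitude
at the end of exercise and hold it through recovery; only the
hockey-stick moves after position 100.  Specifics:

* logarithmic: ln(1+βs)/ln(1+100β), β = 0.2 — the bare logarithm is
  undefined at 0, so the anchoring and scaling are this package's;
* sigmoid: logistic centred at 50 with τ = 8, normalised to [0, amplitude];
* exponential: (e^{rs/100}−1)/(e^r−1), r = 3;
* hockey stick: flat to a breakpoint (default 100), linear to the
  recovery position — the L-curve has no canonical formula, this
  piecewise-linear definition is ours;
* optional early transient dip (half-sine on [0, 25]) to mimic the
  trough-then-rise of short-chain acylcarnitines; off by default.

Noise is multiplicative log-normal with mean 1 and CV `noise_cv`
(default 0.1 — the study does not quantify measurement noise; 10% is a
typical targeted-MS figure), which preserves positivity.  With
probability `p_missing_max` (default 12/47, the study's missingness) a
subject's maximum-load concentration is blanked for all metabolites,
leaving the row as an explicit gap.  A lactate channel calibrated to
medians 1.2 / 8.5 / 7.2 mM (rest / maximum / recovery) provides the
gold-standard reference.

What the generator does **not** emulate: between-subject baseline
variation, group effects (sex, training status), autocorrelated
analytical drift, heteroscedastic noise, or any physiological coupling
between metabolites.  Passing recovery tests therefore demonstrates
correctness of the pipeline's arithmetic and its robustness to
independent multiplicative noise and protocol missingness — not
performance on real cohorts.

Two panels ship as defaults: `demo_panel()` (one metabolite per basis
shape, amplitudes 0.3–0.97, large enough that every shape exceeds the
sustained band) and `study_panel()` (30 metabolites whose shapes and
amplitudes mirror the published kinetic characterisation, with
amplitude = MFC − 1 for monotone shapes).

## Numerical choices and degenerate inputs

* Grid points coinciding with sample positions reproduce sample values
  to 1e−9 relative; the grid step is configurable (the analysis is
  stable under denser grids).
* A constant median curve yields coincident extrema, MFC = 1 and P = 1.
* A non-positive fitted rest concentration aborts the signature (no
  physical interpretation of relative change).
* Series with fewer than 3 usable samples are skipped with a logged
  warning; a grid position covered by no subject is a hard error.
* Reruns with identical input and configuration are bit-identical; the
  configuration (and its hash) is serialised with every result bundle.

## Problem sizes

Default analyses run 47 subjects × 7–30 metabolites on a 118-point
grid; the test suite's noisy-recovery property uses 20 seeds of the
7-metabolite panel and the acceptance script 10 seeds plus one
30-metabolite cohort, sizes at which the full pipeline completes in
seconds while the recovery statistics are stable.

## Known limitations

* The pattern classifier operates on the polynomial fit; narrow
  features (e.g. a dip confined to the first few percent of the axis)
  are attenuated by sparse early sampling, the cohort median and the
  fit, so a trough that is prominent in the true kinetics may fall
  below the early-excursion criterion in the fitted signature.
* The cluster count at a fixed cut height is not a robust statistic
  (see above).
* Exact reproduction of the reference cohort's printed table requires
  the original concentration workbook, which has no public accession;
  the reproduction test documents this dependency and fails without it.
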