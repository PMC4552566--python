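# metakin

Kinetic biomarker discovery from longitudinal exercise metabolomics time
courses.

## The problem

In a graded cycle-ergometry stress test, blood metabolite concentrations
are sampled at rest, at every workload level (+25 W every 3 min, starting
at 50 W) and after a short recovery, for every subject in a cohort.
Because each subject stops at their own maximum workload (anywhere from
150 W to 425 W), the resulting concentration-time curves differ in
length and cannot be compared point by point.  `metakin` implements a
complete discovery pipeline for such data:

1. **Alignment** — each subject's sampling axis is rescaled so rest = 0%,
   the individual maximum workload = 100% and the recovery sample sits at
   a common position (117%, the cohort median of
   100·t<sub>recovery</sub>/t<sub>max</sub>); curves are then linearly
   interpolated onto a shared grid and reduced to pointwise **median
   curves**, which makes the pipeline indifferent to isolated outliers.
2. **Ranking** — the effect size of metabolite *i* is its directional
   **maximum fold change** over the median curve *c*:

   ```
   MFC = c_max / c_min   if argmin(c) < argmax(c)     (≥ 1)
   MFC = c_min / c_max   otherwise                    (≤ 1)
   ```

   Significance is a two-sided Wilcoxon signed-rank test on the
   per-subject interpolated concentrations at the two extremal grid
   positions (exact null for n ≤ 25 without ties, normal approximation
   with continuity correction otherwise), Benjamini–Hochberg adjusted
   across the panel.  Metabolites with max(MFC, 1/MFC) > 1.20 at
   adjusted P < 0.001 are **moderate predictors**, > 1.40 **strong
   predictors** (the volcano-plot thresholds).
3. **Kinetic signatures** — each median curve is smoothed by an
   ordinary-least-squares polynomial f(x) = Σ aᵢxⁱ of degree 9 (fitted
   on the abscissa mapped to [0, 1] for conditioning) and expressed as
   the relative change 100·(f(s) − f(0))/f(0) versus rest.
4. **Shape templates** — signatures are clustered (Euclidean distance on
   relative curves, complete linkage, tree cut at height 35); each
   cluster's median relative curve is a **kinetic shape template**
   labelled with its response pattern: *sustained*, *early*, *halving*,
   *late* or *delayed*.
5. **Classification** — predictor strength and response pattern combine
   into the final call, e.g. "strong predictor, late marker".

A synthetic-cohort generator (`metakin.simulate`) reproduces the study
protocol with known ground-truth kinetics (constant, logarithmic,
sigmoid, linear, quadratic, exponential and hockey-stick basis shapes,
log-normal noise, missing maximum-load samples, a calibrated lactate
gold-standard channel), so every pipeline stage is testable without any
data download.

## Worked example

```python
import metakin as mk

cfg = mk.SimulationConfig(panel=mk.demo_panel(), noise_cv=0.05, seed=42)
cohort, truth = mk.simulate_cohort(cfg)           # 47 subjects, 7 shapes
res = mk.KineticProfileModel(cohort).fit()
print(res.summary())
```

```
Kinetic biomarker profile
======================================================================
metabolites: 7   subjects (max per metabolite): 47
grid: step 1, recovery at 117% (118 points)   signature degree: 9
clusters: 7 at cut height 35 (complete linkage, relative curves)
----------------------------------------------------------------------
metabolite                           MFC    adj. P  classification
----------------------------------------------------------------------
late_exponential_like               1.97  2.89e-09  strong predictor, late marker
late_quadratic_like                 1.39  2.89e-09  moderate predictor, late marker
delayed_like                        1.36  2.89e-09  moderate predictor, delayed marker
late_linear_like                    1.31  2.89e-09  moderate predictor, late marker
halving_like                        1.30  2.89e-09  moderate predictor, halving marker
early_like                          1.29  2.89e-09  moderate predictor, early marker
sustained_like                      1.02  2.14e-01  not selected
----------------------------------------------------------------------
```

Reading the table: `late_exponential_like` was simulated with a 97%
exponential concentration rise toward the end of exercise; the pipeline
estimates its maximum fold change at 1.97 from the noisy cohort,
significant far below the 0.001 cut, above the 1.40 strong-predictor
threshold, and its fitted signature is classified as a late response —
the behaviour of acetylcarnitine in the reference cohort.  The flat
`sustained_like` channel stays near MFC 1 and is not selected.  The
identical adjusted P-values are a feature of the rank-based test: all
six responding channels reach the same extreme rank statistic at n = 47.

`res.save(out_dir)` writes every intermediate table (biomarker ranking,
volcano data, signatures, clusters, templates, heatmap matrix, run
metadata with a config hash); `res.plot(out_dir)` renders the volcano,
signature, template, heatmap and dendrogram figures.

The same workflow is available from the shell:

```sh
metakin simulate --config sim.json --out cohort.csv --truth truth.csv --seed 1
metakin run-all --in cohort.csv --out-dir results/
metakin preprocess|analyze|fit|cluster ...   # stage-by-stage variants
```

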