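# Methods

## Model and rationale

DNAm beta values (fraction methylated, in [0, 1]) at division-tracking CpGs
drift upward with cumulative cell divisions. In normal tissue at cancer
risk, the drift is stochastic: a small, subject-specific subset of the
clock CpGs carries outlying gains that reflect subclonal expansions. The
package models the per-sample score as an order statistic of the clock-CpG
beta distribution — the q-th upper quantile — rather than its mean, because
the mean averages the outlier signal away while the upper quantile tracks
the most advanced subclone regardless of *which* CpGs carry it.

### Clock construction

Selection proceeds in three monotone-shrinking stages; every threshold and
its strictness is part of the contract and covered by boundary tests.

1. **Fetal ground state.** Keep CpGs annotated within the promoter window
   (`tss_window`, default [−200, 0] bp, upstream only; a symmetric-window
   flag admits [−200, +200]) whose beta is strictly below `max_beta`
   (default 0.2) in *every* fetal sample. A missing value disqualifies the
   CpG: constitutive unmethylation cannot be asserted from absent data.
2. **In-vitro mitotic filter.** Per cell line, ordinary least squares of
   beta on population doublings; CpGs need slope > 0 and BH q < 0.05
   (q-values computed within each line) in every line. CpGs with slope > 0
   and *unadjusted* p < 0.05 against days-in-culture in any control
   condition (mitomycin-C arrest, serum deprivation) are then removed —
   these track elapsed time, not division count. Control runs are keyed by
   condition (lines pooled within a condition). A CpG absent from a control
   run is retained with a warning.
3. **In-vivo meta-analysis.** Per cohort, a multiple regression of beta on
   age plus cell-type-fraction covariates (the age coefficient is
   reported). If the fractions sum to exactly 1 the last one is dropped to
   avoid aliasing the intercept. Per-cohort results are combined by the
   directional Stouffer method, z_i = sign(slope_i)·Φ⁻¹(1 − p_i/2),
   z = Σ z_i / √k, two-tailed p = 2(1 − Φ(|z|)); CpGs with z > 0 and
   p < 0.05 form the clock. p-values of exactly 0 are clamped to 1e-300
   before the normal inverse.

Regressions report two-tailed p-values throughout; directionality is
enforced through the slope sign, which reproduces the directional Stouffer
convention exactly. Degenerate regressions (constant response) report
slope 0, p 1 instead of erroring mid-pipeline; an exact noiseless fit with
nonzero slope reports p 0.

### Scoring

The default quantile estimator interpolates linearly between order
statistics at position 1 + (n − 1)q. A `nearest_upper` mode takes the next
order statistic at or above that position; over 20 CpGs at q = 0.95 this is
the per-sample maximum. The interpolating estimator is the package default
for data because it is continuous in q and standard; the nearest-upper mode
is the natural reading for the staged simulation below, whose signal lives
entirely in the top order statistic, and is used there. With 371-CpG-scale
clocks the two differ negligibly.

Samples with under `min_coverage` (default 80%) of the clock CpGs observed
raise an error, or score NA with a warning in lenient mode. Linear clocks
require every weighted CpG unless subset mode is requested (the
EPIC-trained-clock-on-450k situation). All scorers emit orientation
"higher = more divisions"; the 1−mean scorer also reports the raw mean for
hypomethylation-clock display. Hyper- and hypomethylation components of a
two-list clock are reported separately, never combined by a max-deviation
rule, since that rule can silently switch CpG sets between samples.

### Threshold selection

`choose_uq_threshold` scans q over 0.75–0.99 (step 0.01). Effect size is
the difference in mean per-sample UQ score between at-risk and healthy
groups; dispersion is a seeded bootstrap SE of that difference (default 200
resamples within groups). The chosen threshold is the largest grid q
maximizing `effect − penalty·dispersion` with penalty 1 — a concrete
instance of "maximize effect size without compromising sampling
variability", which is otherwise informal.

## Synthetic-data generators

The generators define the study conditions the tests run under; a single
integer seed feeds a named-stream RNG so each generator is independently
reproducible and bit-identical under the same seed.

* **Staged carcinogenesis model** (`simulate_stage_dataset`): 20 CpGs, four
  stages (normal, at-risk, preneoplastic, cancer), 10 samples each by
  default. All betas start from Beta(10, 90) (mean 0.1); per non-normal
  sample, an altered-CpG count is drawn uniformly on 1–3 / 5–10 / 11–17 and
  those CpGs' values are *replaced* by draws from Beta(3, 7) / Beta(5, 5) /
  Beta(8, 2). Altered subsets are drawn independently per sample, giving
  the low inter-subject overlap that motivates the UQ statistic.
  Replacement draws are not clipped against the baseline, so an "altered"
  value can occasionally fall below it.
* **Cell-line study** (`simulate_cellline_pd`): 5,000 CpGs, 100 planted
  mitotic CpGs, 6 lines, 20 sampled passages per line at PD 3–60 (the order
  of the ~30 arrays per line in serially passaged culture studies), per-line
  planted slopes uniform on 0.002–0.004 beta/PD, Gaussian noise sd 0.015,
  per-CpG baselines uniform on 0.05–0.15. Control series (mitomycin,
  serum-deprived) reuse the same grid as days in culture with no drift
  anywhere, and pool lines per condition.
* **In-vivo cohorts** (`simulate_cohort`): 300 samples, ages uniform on
  20–80, planted CpGs drifting 0.002 beta/year, 12 cell-type fractions from
  a symmetric Dirichlet (concentration 10). Optional confounding couples
  the first fraction to age (shift 0.05 across the age range) and makes
  decoy CpGs track that fraction — significant in an unadjusted age
  regression, null once fractions enter as covariates.
* **Fetal ground state** (`simulate_fetal_matrix`): constitutively
  unmethylated promoters, Beta(10, 190) (mean 0.05, sd ≈ 0.015), so the
  ground-state filter tests the window/threshold logic rather than the tail
  of a wider baseline.

What the generators do *not* emulate: array technology artifacts (type-2
probe bias, batch effects), correlated CpG blocks, non-linear drift,
tissue-specific baselines, or realistic missingness patterns. Passing tests
therefore demonstrate the statistical machinery — recovery of planted
signal, calibration of the null, the UQ-vs-mean contrast — not performance
on real arrays.

## Numerical choices

* Per-CpG regressions are fit in bulk via the normal equations (simple OLS
  with pairwise-complete masking; multiple OLS requires complete
  responses — impute first). Single-response multivariate fits go through
  statsmodels OLS. Rank deficiency is detected by QR with pivoting and
  reported with the aliased column names.
* BH q-values come from statsmodels `multipletests(fdr_bh)`; rank tests
  from scipy (`mannwhitneyu`, `wilcoxon`). The rank-sum test enumerates the
  exact null when n₁+n₂ ≤ 12 and there are no ties, else uses the normal
  approximation with tie and continuity correction. The paired clock
  comparison is the signed-rank test across datasets with zero differences
  dropped ("wilcox"; "pratt" optional); an all-zero difference vector
  yields p = 1 (no evidence).
* KNN imputation: neighbours are CpGs; distance is the root mean squared
  difference over shared observed samples (≥ 3 required), donors must be
  observed at the target sample, imputed values are the unweighted mean of
  the k nearest donors, clipped to [0, 1]. Fewer than k candidates is an
  error. Observed cells are never altered.
* Coverage filtering is inclusive at the threshold ("more than X% missing"
  is strict removal) and idempotent.
* Coordinates are 1-based fully closed; `tss_distance` is negative
  upstream. BED-like annotation input converts 0-based starts on read.
* Betas and scores are serialized with 6 decimal places; the missing token
  is configurable text (default "NA") and NaN in memory.
* Beta draws are clipped to the open interval (0, 1) by 1e-9 to keep
  downstream logits/ratios finite.

## Problem sizes

The shipped tests and the acceptance script use: 1,000 random vectors
(length 1–500) for the quantile oracle; 200 samples/stage for the staged
model; the full 5,000-CpG / 100-planted / 6-line / 3-cohort design for
pipeline recovery; n = 10,000 for the Beta moment checks; 60 samples/stage
and 200 bootstrap resamples for the threshold scan. These sizes give
stable pass/fail behaviour across seeds while keeping a full run in the
tens of seconds.

## Known limitations

* The pipeline's sensitivity is intrinsically capped below 1 by the control
  exclusion: a truly mitotic CpG is dropped whenever a control regression
  shows a positive slope with p < 0.05 by chance (~2.5% per control run).
* `mass_multiple_ols` does not handle missing responses; cohort matrices
  must be imputed first.
* The selection thresholds are fixed inputs, not tuned: changing cohort
  sizes or noise levels changes power, and the defaults are calibrated to
  the synthetic designs above only in the sense that those designs are
  realistic.
* Real-data reproduction of a published clock's exact CpG list requires
  the original array datasets and normalization stack (idat processing,
  probe-bias and batch correction, reference-based deconvolution), all of
  which are out of scope here; cell-type fractions are accepted as inputs.
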