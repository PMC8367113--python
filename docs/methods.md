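# Methods

This note documents the models and procedures implemented in `nbdc`, the
assumptions behind the synthetic cohort that drives them, and the numerical
choices a maintainer would want to know about.

## Problem setting

Hourly counts of nearby Bluetooth devices (NBDC) recorded by a phone are a
mixed proxy for social contact, working status, mobility and isolation.  The
pipeline asks two questions about a cohort completing the 8-item Patient
Health Questionnaire (PHQ-8, scored 0–24) every two weeks: (i) which summary
features of the two weeks of counts preceding a questionnaire are associated
with symptom severity, and (ii) how well can the next score be predicted from
those features plus demographics and the last observed score.

## Preprocessing

For each questionnaire we take the 14 calendar days strictly before the
questionnaire date (half-open window `[date − 14, date)`; the questionnaire
day itself is excluded, a convention we fix because inclusivity is otherwise
ambiguous).  A day is **valid** with ≥ 12 distinct observed clock-hours; a
window is **retained** with ≥ 10 valid days.  Missing hours inside valid days
are linearly interpolated between the nearest observed neighbours; leading
and trailing gaps take the nearest observed value (linear interpolation is
undefined with a single anchor).  Invalid days are removed, and the valid
days are concatenated chronologically into one gap-free sequence of
`24 × valid_days` values — a known source of artificial discontinuities for
the spectral features, accepted because zero-filling would distort them more.
Validity counts *observed* hours only, before imputation.  When several scans
fall in one clock-hour they are averaged and rounded half-up.  Records on or
after a configurable cutoff date (default 2020-02-01, to exclude
pandemic-era behaviour change) are dropped.

## The 49 Bluetooth features

* **16 second-order statistics.**  Per valid day: max, min, mean, SD of the
  24 hourly counts; across days: max, min, mean, SD of each daily statistic,
  named `[Second-order]_[Daily]` (e.g. `Mean_Max`).  All SDs use the
  population (divide-by-n) convention; the choice is arbitrary and fixed for
  reproducibility.
* **Multiscale sample entropy, scales 1–24.**  The sequence is coarse-grained
  by averaging non-overlapping blocks of length τ (remainder dropped) and
  sample entropy is computed at each scale: `−ln(A/B)`, where `B` counts
  pairs of m-length templates within Chebyshev tolerance `r` (self-matches
  excluded, template starts limited to `N − m` so the m and m+1 counts are
  comparable) and `A` the same for length m+1.  Parameters are the
  field-standard `m = 2`, `r = 0.2 ×` SD of the scale-1 sequence, with `r`
  held fixed across scales so coarse-graining is not compensated away.  When
  no template pair matches, the Richman–Moorman upper bound
  `ln((N−m)(N−m−1)/2)` is returned so values stay finite.  Low scales measure
  irregularity; high scales reflect periodicity.
* **9 frequency-domain features.**  One-sided periodogram `|DFT|²/N` with
  interior bins doubled, frequency axis in cycles/day (hourly sampling ⇒
  Nyquist at 12).  The DC bin is excluded from all bands and from the
  percentage denominator — with it, the sequence mean would dominate every
  ratio.  Bands are half-open: LF (0, 0.75], MF (0.75, 1.25] — the circadian
  band — and HF (1.25, 12] cycles/day.  Per band: power sum, fraction of
  total non-DC power, and spectral entropy (Shannon entropy of the
  within-band normalized power, divided by `log(#bins)` so 1 = flat).  No
  detrending or tapering is applied before the FFT.  Bins below the FFT
  rounding floor are zeroed so constant sequences report exactly zero
  oscillatory power; a sequence with zero non-DC power yields NaN fractions
  and entropies, flagged rather than fabricated.

Useful invariances (all property-tested): rescaling the sequence leaves the
entropy and ratio/entropy spectral features unchanged and multiplies power
sums by the square of the factor; shifting leaves the entropies, all
SD-type statistics and the non-DC spectrum unchanged.

## Association screening

Each feature enters its own linear mixed-effects model of the PHQ-8 score
with a random participant intercept and fixed covariates age, gender
(binary indicator) and years in education.  Features are z-standardized
internally for conditioning; estimates and SEs are reported on both the raw
and standardized scales.  Significance uses the z-test on the feature
coefficient, with Benjamini–Hochberg step-up adjustment across the family
(α = 0.05).  Constant features and singular fits are flagged and excluded
from the adjustment.  Fits use `statsmodels` `MixedLM`; because its `lbfgs`
optimizer occasionally fails on well-posed problems, fits fall back through
bfgs → lbfgs → powell.

The nested ladder — model A (demographics), B (+ 16 second-order features),
C (+ all 49) — is fitted by maximum likelihood (not REML, as required for
likelihood-ratio tests on fixed effects) on identical rows (listwise
deletion).  The LRT statistic is `2·(llₗ − llₛ)` against χ² with the
parameter-count difference (16, 49, 33) as degrees of freedom.  Model C's
design is exactly rank-deficient (the three band fractions sum to one); the
fit proceeds anyway — the likelihood is well defined, only individual
coefficients are unidentifiable — and the nominal parameter count is used,
mirroring how this feature set is treated in practice.  Hard degeneracies
(constant or duplicated columns) raise an error naming the columns.

## Prediction

**Subset.**  Participants with ≥ 3 retained intervals and a PHQ-8 range ≥ 5
(a clinically meaningful change) enter the prediction task.

**Model.**  A hierarchical Bayesian linear regression on the standardized
outcome:

    y*ᵢⱼ = αⱼ + γⱼ zᵢⱼ + xᵢⱼᵀβ + εᵢⱼ,   εᵢⱼ ~ N(0, σ²)
    αⱼ ~ N(μ_α, τ_α²),   γⱼ ~ N(μ_γ, τ_γ²),   β_k ~ N(0, s²)

with `z` the standardized last observed score, `x` the standardized features
and demographics.  Participant intercepts and last-score slopes are partially
pooled; the 49 feature slopes are population-level with a Gaussian shrinkage
prior (`s = 1` on the standardized scale) — per-participant slopes on 49
features would be unidentifiable at a median of ~8 intervals per person.
Hyperpriors: `μ_α, μ_γ ~ N(0,1)`; all variances `InvGamma(2, 0.5)`
(weakly informative on the standardized scale, and conjugate).  Inference is
a Gibbs sampler in which every conditional is conjugate
(normal / inverse-gamma); multiple independent chains are run and split-R̂
(via ArviZ) is reported for the population-level parameters, with ≤ 1.05 the
acceptance threshold.  Default settings are 4 chains × 1000 draws after 1000
tuning sweeps; cross-validation loops use 2 × 500/500, which pilot checks
showed is the point where posterior-mean Monte-Carlo error stops affecting
model comparisons.  Point predictions are posterior means, clipped to
[0, 24]; unseen participants receive the population means `μ_α, μ_γ`.

The **baseline** model is the same machinery with the feature block removed:
last score + age + gender + education only.

**Last-score predictor.**  A participant's first interval has no predecessor
and is never a test row (both CV schemes start testing at the second or
third interval); in training it is imputed with the participant's first
observed score.  On such rows predictor and response coincide; this is
deliberate — replacing the imputation with a training-mean value was tried
and degraded held-out accuracy for *both* models, because the copied score
teaches exactly the mood-autocorrelation relationship that holds at test
time, where a true previous score always exists.

**Cross-validation.**  Two rolling-origin schemes, both audited
automatically so no training interval of a tested participant is on or after
any of their test intervals:

* *Leave-all-out (LAO):* fold k (k = 2..T) tests every participant's k-th
  interval and trains on their intervals 1..k−1, pooled; T−1 folds.
* *Leave-one-out (LOO):* one fold per participant — train on their first two
  intervals plus everyone else's data, test on their remaining intervals;
  J folds.

RMSE and predicted R² (`1 − SS_res/SS_tot` about the pooled test mean; can
be negative) are pooled across folds, not averaged per fold.

## Synthetic cohort

No public NBDC/PHQ-8 cohort exists, so the generator produces data with the
statistical structure the analysis assumes; every downstream stage is tested
against it.

* **PHQ-8 trajectories:** biweekly, AR(1) on the score scale
  (`ρ = 0.8`, innovation SD 2, population mean 9, start ~ N(9, 5)), clipped
  to [0, 24] and rounded.  Mood autocorrelation is the property the baseline
  predictor exploits.
* **Counts:** Poisson with log-link intensity = participant baseline
  (`~ N(log 4, 0.45)`) + day-level random effect (SD 0.25) + weekday term
  (`~ N(0.15, 0.05)` on Mon–Fri) + circadian sinusoid (amplitude
  `~ N(0.9, 0.15)`, afternoon peak, per-day phase jitter SD 1 h) + hourly
  log-normal noise (SD 0.3).  Magnitudes were chosen once to give realistic
  hourly counts (a few devices, strong circadian rhythm) and are not revisited.
* **Severity coupling:** the standardized latent severity of the
  questionnaire window scales four channels multiplicatively — baseline
  (amount) −0.15, day-level variance −0.15, circadian amplitude −0.25 per
  severity SD, and irregularity +0.5 (phase jitter and hourly noise), so
  worsening symptoms lower the amount, variance and periodicity of the
  series and raise its short-scale entropy.  A null-coupling switch produces
  reference data for calibration checks.
* **Missingness:** days removed with probability 0.05 and single hours with
  probability 0.10, completely at random.
* **Demographics:** age ~ N(48, 14) clipped to [18, 80]; 74% female;
  education ~ N(16, 3.5) years — matching the reported cohort mix.

All randomness flows from one seed through `SeedSequence` spawning; a fixed
configuration reproduces byte-identical CSVs.

What the generator does **not** emulate: informative (severity-dependent)
missingness, site effects, device-type mixtures, weekday/weekend social
structure beyond a single weekday term, pandemic-era behaviour change, or
the real cohort's marginal feature distributions.  Tests passing on this
cohort therefore demonstrate the pipeline's correctness and calibration
under its assumed structure, not the real-world effect sizes.

## Problem sizes used by the test suite

Simulation-based checks run at desk scale, chosen as the smallest sizes at
which the statistical properties are stable: mixed-model calibration uses
100 participants × 8 intervals (coverage) and 50 × 6 (type-I error over 500
replicates); direction-of-effect uses 20 cohorts of 40 participants × 8
questionnaires; model ordering uses 20 cohorts of 30 participants × 11
questionnaires under LAO with 2 × 500/500 sampling.

## Known limitations

* The concatenation of non-adjacent valid days distorts low-frequency
  spectral estimates for windows with many invalid days.
* The Gibbs sampler requires the conjugate inverse-gamma family for scale
  parameters; half-normal scale priors would need a different kernel.
* Feature slopes are global: no participant-level feature effects, and no
  nonlinear (e.g. kernel) extensions.
* LASSO/XGBoost comparators are not implemented; the CV plan interface
  accepts any model that consumes the same train/test tables.
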