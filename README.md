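# nbdc — nearby-Bluetooth-device counts and depressive symptom severity

`nbdc` is an analysis pipeline for longitudinal digital-phenotyping studies
that link the hourly **nearby Bluetooth device count (NBDC)** recorded by a
phone — a mixed proxy for social contact, working status, mobility and
isolation — to **depressive symptom severity** measured biweekly with the
8-item Patient Health Questionnaire (PHQ-8, 0–24).

It is aimed at biostatisticians and mobile-sensing researchers who need the
full chain as tested, reusable code:

1. **Preprocessing** — for each questionnaire, the 14 days of counts before
   it; days with ≥ 12 observed hours are valid, windows with ≥ 10 valid days
   are retained, missing hours are linearly interpolated.
2. **Feature extraction** — 49 features per window: 16 second-order
   statistics of the daily max/min/mean/SD; multiscale sample entropy at
   scales 1–24 (`m = 2`, `r = 0.2 × SD`); and periodogram band power sums,
   fractions and spectral entropies in the LF (0–0.75], MF (0.75–1.25]
   (circadian) and HF (> 1.25 cycles/day) bands.
3. **Association screening** — one linear mixed-effects model per feature
   (random participant intercept; age, gender, education as covariates),
   z-tests with Benjamini–Hochberg FDR correction, plus likelihood-ratio
   tests over the nested ladder demographics → + second-order → + all 49.
4. **Prediction** — a hierarchical Bayesian linear regression
   (partial pooling of participant intercepts and last-score slopes,
   shrinkage priors on feature slopes, conjugate Gibbs sampling) evaluated
   under two rolling-origin cross-validation schemes: leave-all-out (LAO,
   T−1 folds) and leave-one-out (LOO, J folds), scored by pooled RMSE and
   predicted R².

Because no NBDC/PHQ-8 cohort is publicly deposited, the package ships a
**synthetic cohort generator** whose latent severity couples into the count
process along four channels (amount ↓, variance ↓, circadian amplitude ↓,
irregularity ↑ as severity rises).  Every stage is tested against it; see
`docs/methods.md` for the model and its limits.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
60-participant cohort (seed 7) and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_extract_features.py
python analysis/04_associations.py
python analysis/05_prediction_cv.py
```

Selected output from a run of steps 4 and 5:

```
30/49 features significant after FDR correction; strongest:
directions of effect (z): {'amount (Mean_Mean)': -14.13, 'variance (Std_Std)': -8.55,
                           'circadian power (MF_sum)': -12.53, 'irregularity (MSE_1)': 12.72}

nested model ladder (likelihood-ratio tests):
comparison  df_diff  chi2_stat   p  critical_value_05
    B vs A       16    291.431 0.0             26.296
    C vs A       49   1082.012 0.0             66.339
    C vs B       33    790.580 0.0             47.400

LAO: 8 folds (T=9, J=55)
  full     R2=0.884 RMSE=1.317 (n=440)
  baseline R2=0.676 RMSE=2.203 (n=440)
...
Bluetooth features add 0.208 to pooled LAO R2 over the baseline
```

Reading this: as simulated severity rises the count level, day-to-day
variance and circadian (MF-band) power fall while short-scale entropy rises —
each association carries the expected sign with a strongly significant
z-statistic.  The nested-model χ² values exceed their 5% critical values, so
the Bluetooth features improve the fit beyond demographics, and the
nonlinear features improve it beyond the second-order block.  Under
leave-all-out CV the full hierarchical model outperforms the
last-score + demographics baseline by 0.21 pooled R².  (These numbers
describe the synthetic cohort; real-cohort effect sizes will differ.)

The same stages are available as a CLI
(`nbdc simulate|preprocess|features|associate|predict|run`) for use on real
exports with the same CSV columns — scans `(participant_id, timestamp,
count)`, questionnaires `(participant_id, date, score)`, demographics
`(participant_id, age, gender, education_years)`.

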