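"""Time-series CV plans, the hierarchical Bayesian model, and metrics."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_interval_frame
from nbdc.errors import ContractViolation, ValidationError
from nbdc.prediction import (
    BASELINE_PREDICTORS,
    HierModelSpec,
    add_last_phq8,
    evaluate,
    fit_hierarchical,
    lao_splits,
    loo_splits,
    predict,
    select_prediction_subset,
    validate_plan,
)


class TestSubsetSelection:
    def test_boundary_inclusion(self):
        df = pd.DataFrame(
            {
                "participant_id": ["A"] * 3 + ["B"] * 2 + ["C"] * 5,
                "questionnaire_date": pd.date_range("2019-01-01", periods=10, freq="14D"),
                "phq8_score": [4, 6, 9] + [0, 24] + [7, 8, 9, 10, 11],
            }
        )
        # A: 3 intervals, range 5 -> in; B: 2 intervals -> out; C: range 4 -> out
        assert select_prediction_subset(df) == ["A"]


class TestCVPlans:
    def test_lao_fold_count_follows_max_interval_count(self):
        t_per = {f"P{i}": 3 + (i % 8) for i in range(40)}
        t_per["P40"] = 27
        df = make_interval_frame(t_per)
        plan = lao_splits(df)
        assert plan.T == 27
        assert len(plan.folds) == 26
        validate_plan(plan, df)

    def test_lao_participant_appears_only_while_it_has_data(self):
        df = make_interval_frame({"A": 3, "B": 5})
        plan = lao_splits(df)
        pids = df["participant_id"]
        a_test_folds = [
            k for k, f in enumerate(plan.folds)
            if any(pids.iloc[list(f.test_ids)] == "A")
        ]
        assert a_test_folds == [0, 1]  # folds k=2 and k=3

    def test_loo_one_fold_per_participant(self):
        df = make_interval_frame({f"P{i:03d}": 3 + (i % 5) for i in range(183)})
        plan = loo_splits(df)
        assert plan.J == 183
        assert len(plan.folds) == 183
        validate_plan(plan, df)

    def test_loo_test_set_is_everything_after_second_interval(self):
        df = make_interval_frame({"A": 5, "B": 4, "C": 3})
        plan = loo_splits(df)
        sizes = sorted(len(f.test_ids) for f in plan.folds)
        assert sizes == [1, 2, 3]
        # the target participant's later intervals never leak into training
        pids = df["participant_id"]
        for fold in plan.folds:
            test_pid = pids.iloc[list(fold.test_ids)].unique()
            assert len(test_pid) == 1
            own_train = [r for r in fold.train_ids if pids.iloc[r] == test_pid[0]]
            assert len(own_train) == 2

    def test_loo_requires_three_intervals(self):
        with pytest.raises(ContractViolation):
            loo_splits(make_interval_frame({"A": 2, "B": 4}))

    def test_leakage_audit_catches_shuffled_fold(self):
        df = make_interval_frame({"A": 4, "B": 4})
        plan = lao_splits(df)
        bad = plan.folds[0]
        plan.folds[0] = type(bad)(train_ids=bad.test_ids, test_ids=bad.train_ids)
        with pytest.raises(ContractViolation):
            validate_plan(plan, df)


class TestLastScore:
    def test_shifted_scores_and_first_interval_imputation(self):
        df = make_interval_frame({"A": 3})
        df["phq8_score"] = [5, 9, 13]
        out = add_last_phq8(df)
        assert out["last_phq8"].tolist() == [5.0, 5.0, 9.0]


def _linear_cohort(rng, J=40, t=5, slope=0.8, noise=1.0):
    rows = []
    for j in range(J):
        a_j = rng.normal(0, 2)
        x = rng.normal(0, 1, t)
        last = rng.normal(9, 4, t)
        y = 9 + a_j + slope * x + 0.3 * (last - 9) + rng.normal(0, noise, t)
        for k in range(t):
            rows.append((f"P{j:03d}", k, float(y[k]), float(x[k]), float(last[k]),
                         50.0, 1.0, 16.0))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "questionnaire_date", "phq8_score", "feat",
                 "last_phq8", "age", "gender_female", "education_years"],
    )


FAST = dict(draws=300, tune=300, chains=2)


class TestHierarchicalModel:
    def test_recovers_population_slope(self):
        rng = np.random.default_rng(77)
        df = _linear_cohort(rng, J=60, t=6)
        fit = fit_hierarchical(df, HierModelSpec(feature_names=("feat",), seed=1, **FAST))
        est = fit.coefficients_raw()["feat"]
        lo, hi = fit.beta_interval_raw("feat")
        assert abs(est - 0.8) < 0.1
        assert lo <= 0.8 <= hi
        assert max(fit.rhat.values()) < 1.05

    def test_pure_noise_slopes_shrink_to_zero(self):
        rng = np.random.default_rng(78)
        df = _linear_cohort(rng, J=30, t=5, slope=0.0)
        for i in range(8):
            df[f"noise_{i}"] = rng.normal(size=len(df))
        names = tuple(f"noise_{i}" for i in range(8))
        spec = HierModelSpec(feature_names=names, seed=2, **FAST)
        fit = fit_hierarchical(df, spec)
        mean_abs = np.abs(fit.beta_mean[: len(names)]).mean()
        assert mean_abs < 0.5 * spec.slope_prior_sd

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(79)
        df = _linear_cohort(rng, J=20, t=4)
        spec = HierModelSpec(feature_names=("feat",), seed=3, draws=100, tune=100, chains=2)
        a = fit_hierarchical(df, spec)
        b = fit_hierarchical(df, spec)
        assert np.array_equal(a.beta_draws, b.beta_draws)
        assert a.alpha_mean == b.alpha_mean

    def test_near_noiseless_interpolation(self):
        """A heavily replicated training point is predicted almost exactly."""
        rng = np.random.default_rng(80)
        df = _linear_cohort(rng, J=30, t=8, noise=0.05)
        fit = fit_hierarchical(df, HierModelSpec(feature_names=("feat",), seed=4, **FAST))
        yhat = predict(fit, df)
        resid = np.abs(yhat - df["phq8_score"].to_numpy())
        assert np.median(resid) < 0.5

    def test_unseen_participant_uses_population_terms(self):
        rng = np.random.default_rng(81)
        df = _linear_cohort(rng, J=20, t=4)
        fit = fit_hierarchical(df, HierModelSpec(feature_names=("feat",), seed=5,
                                                 draws=100, tune=100, chains=1))
        row = df.iloc[[0]].assign(participant_id="UNSEEN")
        expected_alpha = fit.mu_alpha
        x = (row[list(fit.predictor_names)].to_numpy(float) - fit.x_center) / fit.x_scale
        z = (row["last_phq8"].to_numpy(float) - fit.z_center) / fit.z_scale
        manual = (expected_alpha + fit.mu_gamma * z + x @ fit.beta_mean) * fit.y_scale + fit.y_center
        assert predict(fit, row, clip=False)[0] == pytest.approx(float(manual[0]))

    def test_predictions_clipped_to_score_range(self):
        rng = np.random.default_rng(82)
        df = _linear_cohort(rng, J=20, t=4)
        fit = fit_hierarchical(df, HierModelSpec(feature_names=("feat",), seed=6,
                                                 draws=100, tune=100, chains=1))
        wild = df.iloc[[0]].assign(feat=100.0, last_phq8=50.0)
        assert 0.0 <= predict(fit, wild)[0] <= 24.0

    def test_baseline_predictor_census(self):
        rng = np.random.default_rng(83)
        df = _linear_cohort(rng, J=20, t=4)
        fit = fit_hierarchical(df, HierModelSpec(feature_names=(), seed=7,
                                                 draws=100, tune=100, chains=1))
        model_predictors = set(fit.predictor_names) | {"last_phq8"}
        assert model_predictors == set(BASELINE_PREDICTORS)
        assert len(model_predictors) == 4

    def test_missing_predictor_column_rejected(self):
        rng = np.random.default_rng(84)
        df = _linear_cohort(rng, J=20, t=4)
        with pytest.raises(ValidationError):
            fit_hierarchical(df, HierModelSpec(feature_names=("absent",), seed=8,
                                               draws=50, tune=50, chains=1))


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([3.0, 7.0, 11.0])
        m = evaluate(y, y)
        assert m.r2 == 1.0 and m.rmse == 0.0 and m.n_test == 3

    def test_mean_prediction_scores_zero(self):
        y = np.array([2.0, 4.0, 9.0, 13.0])
        m = evaluate(np.full(4, y.mean()), y)
        assert m.r2 == pytest.approx(0.0)

    def test_worse_than_mean_is_negative(self):
        y = np.array([2.0, 4.0, 9.0, 13.0])
        m = evaluate(np.array([13.0, 9.0, 4.0, 2.0]), y)
        assert m.r2 < 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            evaluate(np.ones(3), np.ones(4))
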