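"""PHQ-8 prediction: hierarchical Bayesian regression under time-series CV.

Two rolling-origin cross-validation schemes evaluate the forecasts:

* **LAO** (leave-all-out): fold k (k = 2..T) tests every participant's k-th
  questionnaire interval, training on that participant's intervals 1..k-1,
  pooled across participants; T-1 folds, where T is the maximum number of
  intervals per participant.
* **LOO** (leave-one-out): one fold per participant; training data are the
  participant's first two intervals plus all intervals of every other
  participant, and the test set is the participant's remaining intervals;
  J folds.

The predictive model is a hierarchical Bayesian linear regression with a
partially pooled intercept and a partially pooled slope on the last observed
PHQ-8 score per participant, and population-level slopes with a Gaussian
shrinkage prior on the standardized Bluetooth features and demographics.
Posterior inference is by a conjugate Gibbs sampler (normal / inverse-gamma
updates); split-R-hat diagnostics on the population-level parameters are
computed with ArviZ.  The baseline model drops the feature block and keeps
last PHQ-8 + demographics only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractViolation, ValidationError

__all__ = [
    "Fold",
    "CVPlan",
    "HierModelSpec",
    "PosteriorFit",
    "PredictionMetrics",
    "BASELINE_PREDICTORS",
    "select_prediction_subset",
    "lao_splits",
    "loo_splits",
    "validate_plan",
    "add_last_phq8",
    "fit_hierarchical",
    "predict",
    "evaluate",
    "run_cv",
]

BASELINE_PREDICTORS = ("last_phq8", "age", "gender_female", "education_years")
_DEMOGRAPHICS = ("age", "gender_female", "education_years")


@dataclass(frozen=True)
class Fold:
    train_ids: tuple[int, ...]
    test_ids: tuple[int, ...]


@dataclass
class CVPlan:
    scheme: str  # "LAO" or "LOO"
    folds: list[Fold]
    t_per_participant: dict[str, int]
    T: int  # max intervals of any subset participant
    J: int  # number of subset participants


@dataclass(frozen=True)
class HierModelSpec:
    """Sampler and predictor settings for the hierarchical model.

    ``feature_names`` empty means the baseline model (last PHQ-8 +
    demographics only).  Scales are on the internally standardized outcome;
    the shrinkage prior on population slopes is Normal(0, slope_prior_sd^2).
    """

    feature_names: tuple[str, ...] = ()
    draws: int = 1000
    tune: int = 1000
    chains: int = 4
    seed: int = 0
    slope_prior_sd: float = 1.0
    hyper_a: float = 2.0  # inverse-gamma shape for variance components
    hyper_b: float = 0.5  # inverse-gamma scale


@dataclass
class PosteriorFit:
    spec: HierModelSpec
    predictor_names: tuple[str, ...]
    beta_mean: np.ndarray  # standardized-scale population slopes
    beta_draws: np.ndarray  # (chains, draws, p)
    alpha_mean: dict[str, float]  # per-participant intercept (standardized y)
    gamma_mean: dict[str, float]  # per-participant slope on last_phq8
    mu_alpha: float
    mu_gamma: float
    sigma: float
    rhat: dict[str, float]
    x_center: np.ndarray
    x_scale: np.ndarray
    z_center: float
    z_scale: float
    y_center: float
    y_scale: float

    def coefficients_raw(self) -> pd.Series:
        """Population slopes back-transformed to raw predictor / score units."""
        return pd.Series(
            self.beta_mean * self.y_scale / self.x_scale, index=self.predictor_names
        )

    def beta_interval_raw(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        """Equal-tailed posterior credible interval on the raw scale."""
        j = self.predictor_names.index(name)
        draws = self.beta_draws[..., j].ravel() * self.y_scale / self.x_scale[j]
        lo, hi = np.quantile(draws, [(1 - prob) / 2, 1 - (1 - prob) / 2])
        return float(lo), float(hi)


@dataclass
class PredictionMetrics:
    r2: float
    rmse: float
    n_test: int


# ---------------------------------------------------------------------------
# subset selection and CV plans


def select_prediction_subset(
    intervals: pd.DataFrame, min_intervals: int = 3, min_score_range: int = 5
) -> list[str]:
    """Participants with enough intervals and clinically meaningful score change.

    Keeps participants with at least ``min_intervals`` retained intervals whose
    PHQ-8 scores span a range of at least ``min_score_range`` points.
    """
    keep = []
    for pid, grp in intervals.groupby("participant_id", sort=False):
        if len(grp) < min_intervals:
            continue
        if grp["phq8_score"].max() - grp["phq8_score"].min() < min_score_range:
            continue
        keep.append(pid)
    return keep


def _ordered(intervals: pd.DataFrame) -> pd.DataFrame:
    df = intervals.reset_index(drop=True).copy()
    df["_row"] = df.index
    df = df.sort_values(["participant_id", "questionnaire_date"], kind="stable")
    dup = df.duplicated(subset=["participant_id", "questionnaire_date"])
    if dup.any():
        raise ValidationError("duplicate questionnaire dates within a participant")
    df["_k"] = df.groupby("participant_id").cumcount() + 1
    return df


def lao_splits(intervals: pd.DataFrame) -> CVPlan:
    """Leave-all-out rolling-origin plan: fold k tests every k-th interval."""
    if intervals.empty:
        raise ValidationError("empty interval table")
    df = _ordered(intervals)
    t_per = df.groupby("participant_id")["_k"].max().to_dict()
    T = max(t_per.values())
    folds = []
    for k in range(2, T + 1):
        eligible = df.groupby("participant_id")["_k"].transform("max") >= k
        sub = df[eligible]
        test = tuple(sub.loc[sub["_k"] == k, "_row"])
        train = tuple(sub.loc[sub["_k"] < k, "_row"])
        folds.append(Fold(train_ids=train, test_ids=test))
    return CVPlan("LAO", folds, t_per, T=T, J=len(t_per))


def loo_splits(intervals: pd.DataFrame) -> CVPlan:
    """Leave-one-out plan: per participant, train on their first two intervals
    plus everyone else's data, test on their remaining intervals."""
    if intervals.empty:
        raise ValidationError("empty interval table")
    df = _ordered(intervals)
    t_per = df.groupby("participant_id")["_k"].max().to_dict()
    if min(t_per.values()) < 3:
        raise ContractViolation("every subset participant must have >= 3 intervals")
    folds = []
    for pid in t_per:
        own = df["participant_id"] == pid
        train = tuple(df.loc[(own & (df["_k"] <= 2)) | ~own, "_row"])
        test = tuple(df.loc[own & (df["_k"] > 2), "_row"])
        folds.append(Fold(train_ids=train, test_ids=test))
    return CVPlan("LOO", folds, t_per, T=max(t_per.values()), J=len(t_per))


def validate_plan(plan: CVPlan, intervals: pd.DataFrame) -> None:
    """Audit the temporal-leakage invariant: for every participant under test,
    all of their training intervals predate all of their test intervals."""
    df = intervals.reset_index(drop=True)
    dates = pd.to_datetime(df["questionnaire_date"])
    pids = df["participant_id"]
    for i, fold in enumerate(plan.folds):
        train, test = list(fold.train_ids), list(fold.test_ids)
        if set(train) & set(test):
            raise ContractViolation(f"fold {i}: overlapping train and test rows")
        for pid in pids.iloc[test].unique():
            tr = [r for r in train if pids.iloc[r] == pid]
            if not tr:
                continue
            if dates.iloc[tr].max() >= dates.iloc[test].loc[pids.iloc[test] == pid].min():
                raise ContractViolation(
                    f"fold {i}: training data of {pid} does not predate its test data"
                )


def add_last_phq8(intervals: pd.DataFrame) -> pd.DataFrame:
    """Attach the most recent earlier PHQ-8 score of each participant.

    A participant's first interval has no predecessor (it is never a test row
    under either scheme, which start testing at the second / third interval).
    Such rows take the participant's first observed score (their own score) and
    are flagged in ``last_phq8_imputed``.  On these training rows predictor and
    response coincide, which simply teaches the model the mood autocorrelation
    it needs at test time, where the true previous score is always available.
    """
    df = _ordered(intervals)
    df["last_phq8"] = (
        df.groupby("participant_id")["phq8_score"].shift(1).astype(float)
    )
    df["last_phq8_imputed"] = df["last_phq8"].isna()
    first = df.groupby("participant_id")["phq8_score"].transform("first")
    df["last_phq8"] = df["last_phq8"].fillna(first.astype(float))
    return df.sort_values("_row").set_index("_row", drop=True).rename_axis(None)


# ---------------------------------------------------------------------------
# Gibbs sampler


def _invgamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    return scale / rng.gamma(shape)


def fit_hierarchical(train: pd.DataFrame, spec: HierModelSpec) -> PosteriorFit:
    """Fit the partial-pooling regression by conjugate Gibbs sampling.

    Model (on the standardized outcome y*):
        y*_ij = alpha_j + gamma_j z_ij + x_ij' beta + eps,  eps ~ N(0, sigma^2)
        alpha_j ~ N(mu_alpha, tau_alpha^2),  gamma_j ~ N(mu_gamma, tau_gamma^2)
        beta_k ~ N(0, slope_prior_sd^2)   (shrinkage on population slopes)
        mu_alpha, mu_gamma ~ N(0, 1); variances ~ InvGamma(hyper_a, hyper_b)

    z is the standardized last observed PHQ-8 score; x holds the standardized
    features and demographics.  Multiple independent chains are run and
    split-R-hat is computed on the population-level parameters.
    """
    if train.empty:
        raise ValidationError("empty training table")
    if train["participant_id"].nunique() < 2:
        raise ValidationError("need at least two participants to pool")

    predictor_names = tuple(spec.feature_names) + _DEMOGRAPHICS
    for col in predictor_names + ("last_phq8", "phq8_score"):
        if col not in train.columns:
            raise ValidationError(f"training table lacks predictor column {col!r}")

    y_raw = train["phq8_score"].to_numpy(dtype=float)
    y_center, y_scale = float(y_raw.mean()), float(y_raw.std())
    if y_scale == 0:
        y_scale = 1.0
    y = (y_raw - y_center) / y_scale

    x_raw = train[list(predictor_names)].to_numpy(dtype=float)
    z_raw = train["last_phq8"].to_numpy(dtype=float)
    xz = np.column_stack([x_raw, z_raw])
    center = xz.mean(axis=0)
    scale = xz.std(axis=0)
    scale[scale == 0] = 1.0
    xz = (xz - center) / scale
    x, z = xz[:, :-1], xz[:, -1]

    pids = train["participant_id"].to_numpy()
    participants, codes = np.unique(pids, return_inverse=True)
    n, p = x.shape
    n_j = np.bincount(codes).astype(float)
    j_count = participants.size

    xtx = x.T @ x
    a0, b0 = spec.hyper_a, spec.hyper_b
    s2_beta = spec.slope_prior_sd**2

    root = np.random.SeedSequence(spec.seed)
    chain_draws_beta = np.empty((spec.chains, spec.draws, p))
    chain_pop = {
        k: np.empty((spec.chains, spec.draws))
        for k in ("mu_alpha", "mu_gamma", "sigma2", "tau_alpha2", "tau_gamma2")
    }
    alpha_acc = np.zeros(j_count)
    gamma_acc = np.zeros(j_count)

    for c, seq in enumerate(root.spawn(spec.chains)):
        rng = np.random.default_rng(seq)
        beta = np.zeros(p)
        alpha = np.zeros(j_count)
        gamma = np.zeros(j_count)
        mu_a = mu_g = 0.0
        tau_a2 = tau_g2 = 0.25
        sigma2 = 1.0
        for it in range(spec.tune + spec.draws):
            # population slopes
            r = y - alpha[codes] - gamma[codes] * z
            prec = xtx / sigma2 + np.eye(p) / s2_beta
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, x.T @ r / sigma2)
            beta = mean + np.linalg.solve(chol.T, rng.standard_normal(p))
            # participant-level intercept and last-score slope (2x2 per j)
            resid = y - x @ beta
            s_z = np.bincount(codes, weights=z, minlength=j_count)
            s_zz = np.bincount(codes, weights=z * z, minlength=j_count)
            s_r = np.bincount(codes, weights=resid, minlength=j_count)
            s_zr = np.bincount(codes, weights=z * resid, minlength=j_count)
            p11 = n_j / sigma2 + 1.0 / tau_a2
            p22 = s_zz / sigma2 + 1.0 / tau_g2
            p12 = s_z / sigma2
            r1 = s_r / sigma2 + mu_a / tau_a2
            r2 = s_zr / sigma2 + mu_g / tau_g2
            det = p11 * p22 - p12 * p12
            m1 = (p22 * r1 - p12 * r2) / det
            m2 = (p11 * r2 - p12 * r1) / det
            l11 = np.sqrt(p11)
            l21 = p12 / l11
            l22 = np.sqrt(np.maximum(p22 - l21**2, 1e-12))
            e2 = rng.standard_normal(j_count)
            e1 = rng.standard_normal(j_count)
            # sample via inverse of the Cholesky factor of the precision
            u2 = e2 / l22
            u1 = (e1 - l21 * u2) / l11
            alpha = m1 + u1
            gamma = m2 + u2
            # hyperpriors
            va = 1.0 / (j_count / tau_a2 + 1.0)
            mu_a = rng.normal(va * alpha.sum() / tau_a2, np.sqrt(va))
            vg = 1.0 / (j_count / tau_g2 + 1.0)
            mu_g = rng.normal(vg * gamma.sum() / tau_g2, np.sqrt(vg))
            tau_a2 = _invgamma(rng, a0 + j_count / 2, b0 + ((alpha - mu_a) ** 2).sum() / 2)
            tau_g2 = _invgamma(rng, a0 + j_count / 2, b0 + ((gamma - mu_g) ** 2).sum() / 2)
            err = resid - alpha[codes] - gamma[codes] * z
            sigma2 = _invgamma(rng, a0 + n / 2, b0 + (err**2).sum() / 2)
            if it >= spec.tune:
                d = it - spec.tune
                chain_draws_beta[c, d] = beta
                chain_pop["mu_alpha"][c, d] = mu_a
                chain_pop["mu_gamma"][c, d] = mu_g
                chain_pop["sigma2"][c, d] = sigma2
                chain_pop["tau_alpha2"][c, d] = tau_a2
                chain_pop["tau_gamma2"][c, d] = tau_g2
                alpha_acc += alpha
                gamma_acc += gamma

    total = spec.chains * spec.draws
    rhat = _split_rhat(chain_pop, chain_draws_beta)
    return PosteriorFit(
        spec=spec,
        predictor_names=tuple(predictor_names),
        beta_mean=chain_draws_beta.reshape(total, p).mean(axis=0),
        beta_draws=chain_draws_beta,
        alpha_mean=dict(zip(participants, alpha_acc / total)),
        gamma_mean=dict(zip(participants, gamma_acc / total)),
        mu_alpha=float(chain_pop["mu_alpha"].mean()),
        mu_gamma=float(chain_pop["mu_gamma"].mean()),
        sigma=float(np.sqrt(chain_pop["sigma2"]).mean()),
        rhat=rhat,
        x_center=center[:-1].copy(),
        x_scale=scale[:-1].copy(),
        z_center=float(center[-1]),
        z_scale=float(scale[-1]),
        y_center=y_center,
        y_scale=y_scale,
    )


def _split_rhat(chain_pop: dict[str, np.ndarray], beta: np.ndarray) -> dict[str, float]:
    import arviz as az

    if next(iter(chain_pop.values())).shape[0] < 2:
        return {}  # split-R-hat needs at least two chains
    out = {}
    for k, v in chain_pop.items():
        out[k] = float(az.rhat(az.convert_to_dataset(v[..., None]))["x"].values[0])
    out["beta_max"] = float(
        np.nanmax(az.rhat(az.convert_to_dataset(beta))["x"].values)
    )
    return out


def predict(fit: PosteriorFit, test: pd.DataFrame, clip: bool = True) -> np.ndarray:
    """Posterior-mean point predictions for test intervals.

    Test predictors are standardized with the training statistics.  A
    participant unseen during training receives the population-level intercept
    and slope means.  Predictions are clipped to the [0, 24] score range for
    reporting.
    """
    missing = [c for c in fit.predictor_names + ("last_phq8",) if c not in test.columns]
    if missing:
        raise ValidationError(f"test table lacks predictor columns {missing}")
    x = (test[list(fit.predictor_names)].to_numpy(dtype=float) - fit.x_center) / fit.x_scale
    z = (test["last_phq8"].to_numpy(dtype=float) - fit.z_center) / fit.z_scale
    alpha = np.array(
        [fit.alpha_mean.get(pid, fit.mu_alpha) for pid in test["participant_id"]]
    )
    gamma = np.array(
        [fit.gamma_mean.get(pid, fit.mu_gamma) for pid in test["participant_id"]]
    )
    y_star = alpha + gamma * z + x @ fit.beta_mean
    y = y_star * fit.y_scale + fit.y_center
    return np.clip(y, 0.0, 24.0) if clip else y


def evaluate(predictions: np.ndarray, truths: np.ndarray) -> PredictionMetrics:
    """Pooled RMSE and predicted R^2 (1 - SS_res/SS_tot about the test mean)."""
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if predictions.shape != truths.shape:
        raise ValidationError("prediction and truth vectors differ in length")
    n = truths.size
    rmse = float(np.sqrt(np.mean((predictions - truths) ** 2)))
    if n < 2 or truths.std() == 0:
        return PredictionMetrics(r2=float("nan"), rmse=rmse, n_test=n)
    ss_res = float(((truths - predictions) ** 2).sum())
    ss_tot = float(((truths - truths.mean()) ** 2).sum())
    return PredictionMetrics(r2=1.0 - ss_res / ss_tot, rmse=rmse, n_test=n)


def run_cv(
    table: pd.DataFrame,
    plan: CVPlan,
    spec: HierModelSpec,
) -> tuple[pd.DataFrame, PredictionMetrics]:
    """Fit and predict across every fold of a CV plan; metrics pooled over folds."""
    df = table.reset_index(drop=True)
    rows = []
    seeds = np.random.SeedSequence(spec.seed).generate_state(len(plan.folds)) % (2**31)
    for i, fold in enumerate(plan.folds):
        if not fold.test_ids:
            continue
        fold_spec = HierModelSpec(
            feature_names=spec.feature_names,
            draws=spec.draws,
            tune=spec.tune,
            chains=spec.chains,
            seed=int(seeds[i]),
            slope_prior_sd=spec.slope_prior_sd,
            hyper_a=spec.hyper_a,
            hyper_b=spec.hyper_b,
        )
        fit = fit_hierarchical(df.loc[list(fold.train_ids)], fold_spec)
        test = df.loc[list(fold.test_ids)]
        yhat = predict(fit, test)
        for rid, pred, truth in zip(fold.test_ids, yhat, test["phq8_score"]):
            rows.append((i, rid, float(pred), float(truth)))
    preds = pd.DataFrame(rows, columns=["fold", "row", "prediction", "truth"])
    metrics = evaluate(preds["prediction"].to_numpy(), preds["truth"].to_numpy())
    return preds, metrics
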