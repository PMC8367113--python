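"""Association screening: pairwise linear mixed-effects models, FDR, nested LRTs.

Each Bluetooth feature is regressed against the PHQ-8 score in its own linear
mixed-effects model with a random participant intercept and baseline age,
gender and years in education as fixed covariates.  Significance of the
feature coefficient uses a z-test; the Benjamini-Hochberg step-up procedure
controls the false-discovery rate across features.  A ladder of three nested
models (demographics only; + 16 second-order features; + all 49 features) is
compared by likelihood-ratio tests, fitted by maximum likelihood on identical
rows.

Features are z-standardized internally for numerical stability; reported
estimates and standard errors are back-transformed to the raw feature scale
(the standardized versions are carried alongside).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import ContractViolation, ValidationError

__all__ = [
    "AssociationResult",
    "LRTResult",
    "DEFAULT_COVARIATES",
    "encode_covariates",
    "pairwise_lmm",
    "bh_adjust",
    "associate_all",
    "fit_nested_models",
    "likelihood_ratio_test",
    "chi2_critical",
]

DEFAULT_COVARIATES = ("age", "gender_female", "education_years")

_OPTIMIZERS = ("bfgs", "lbfgs", "powell")


def _fit_with_fallback(model: MixedLM, reml: bool, maxiter: int = 200):
    """Fit a mixed model, falling back through optimizers on numerical failure."""
    last: Exception | None = None
    for method in _OPTIMIZERS:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", UserWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                return model.fit(reml=reml, method=method, maxiter=maxiter)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last = exc
    raise last  # type: ignore[misc]


@dataclass
class AssociationResult:
    feature_name: str
    estimate: float  # score units per raw feature unit
    se: float
    z: float
    p_raw: float
    p_adjusted: float  # NaN until BH adjustment
    estimate_std: float  # score units per feature SD
    se_std: float
    flagged: bool = False
    note: str = ""


@dataclass
class LRTResult:
    model_pair: str
    df_diff: int
    chi2_stat: float
    p: float
    critical_value_05: float


def encode_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Add the binary gender indicator expected by the model covariates."""
    out = table.copy()
    if "gender_female" not in out.columns:
        if "gender" not in out.columns:
            raise ValidationError("table lacks both 'gender' and 'gender_female'")
        out["gender_female"] = (out["gender"].astype(str) == "female").astype(float)
    return out


def pairwise_lmm(
    table: pd.DataFrame,
    feature: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    outcome: str = "phq8_score",
    group: str = "participant_id",
    reml: bool = True,
) -> AssociationResult:
    """Regress the PHQ-8 score on one feature with a random participant intercept.

    A zero-variance feature (or a singular / non-converged fit) is returned
    flagged with NaN statistics so the caller can exclude it from FDR
    adjustment.
    """
    table = encode_covariates(table)
    cols = [outcome, feature, *covariates, group]
    data = table[cols].dropna()
    x = data[feature].to_numpy(dtype=float)
    sd = x.std()
    if sd == 0:
        return AssociationResult(
            feature, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
            flagged=True, note="constant feature",
        )
    exog = pd.DataFrame({"const": 1.0, feature: (x - x.mean()) / sd})
    for c in covariates:
        exog[c] = data[c].to_numpy(dtype=float)
    try:
        fit = _fit_with_fallback(
            MixedLM(data[outcome].to_numpy(dtype=float), exog, groups=data[group]),
            reml=reml,
        )
        est_std = float(fit.fe_params[feature])
        se_std = float(fit.bse_fe[feature])
    except (np.linalg.LinAlgError, ValueError) as exc:
        return AssociationResult(
            feature, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
            flagged=True, note=f"singular fit: {exc}",
        )
    if not np.isfinite(est_std) or not np.isfinite(se_std) or se_std == 0:
        return AssociationResult(
            feature, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
            flagged=True, note="non-finite estimate",
        )
    z = est_std / se_std
    p = 2.0 * stats.norm.sf(abs(z))
    return AssociationResult(
        feature_name=feature,
        estimate=est_std / sd,
        se=se_std / sd,
        z=float(z),
        p_raw=float(p),
        p_adjusted=np.nan,
        estimate_std=est_std,
        se_std=se_std,
    )


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def associate_all(
    table: pd.DataFrame,
    feature_names: tuple[str, ...] | list[str],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    reml: bool = True,
) -> pd.DataFrame:
    """Pairwise screening of every feature with BH adjustment across the family."""
    results = [pairwise_lmm(table, f, covariates, reml=reml) for f in feature_names]
    ok = [r for r in results if not r.flagged]
    if ok:
        adjusted = bh_adjust(np.array([r.p_raw for r in ok]))
        for r, q in zip(ok, adjusted):
            r.p_adjusted = float(q)
    return pd.DataFrame(
        {
            "feature_name": [r.feature_name for r in results],
            "estimate": [r.estimate for r in results],
            "se": [r.se for r in results],
            "z": [r.z for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "estimate_std": [r.estimate_std for r in results],
            "se_std": [r.se_std for r in results],
            "flagged": [r.flagged for r in results],
            "note": [r.note for r in results],
        }
    )


def _ml_mixed_fit(
    data: pd.DataFrame,
    predictors: list[str],
    outcome: str,
    group: str,
):
    exog = pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
    for c in predictors:
        col = data[c].to_numpy(dtype=float)
        sd = col.std()
        exog[c] = (col - col.mean()) / sd if sd > 0 else 0.0
    # hard degeneracies (constant or duplicated predictors) are user errors;
    # the structural sum-to-one identity of the band fractions is tolerated,
    # matching common mixed-model practice for this feature set
    arr = exog.to_numpy()
    constant = [c for c, col in zip(exog.columns[1:], arr[:, 1:].T) if col.std() == 0]
    if constant:
        raise ValidationError(f"rank-deficient design; collinear columns: {constant}")
    seen: dict[bytes, str] = {}
    for c, col in zip(exog.columns, arr.T):
        key = np.round(col, 12).tobytes()
        if key in seen:
            raise ValidationError(
                f"rank-deficient design; collinear columns: ['{seen[key]}', '{c}']"
            )
        seen[key] = c
    return _fit_with_fallback(
        MixedLM(data[outcome].to_numpy(dtype=float), exog, groups=data[group]),
        reml=False,
        maxiter=500,
    )


def fit_nested_models(
    table: pd.DataFrame,
    second_order_names: list[str] | tuple[str, ...],
    all_feature_names: list[str] | tuple[str, ...],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    outcome: str = "phq8_score",
    group: str = "participant_id",
):
    """Fit the nested ladder A (demographics), B (+ second-order), C (+ all).

    All three fits use maximum likelihood (not REML) on identical rows, as
    required for likelihood-ratio tests on fixed effects.
    """
    table = encode_covariates(table)
    cols = [outcome, group, *covariates, *all_feature_names]
    data = table[list(dict.fromkeys(cols))].dropna()
    model_a = _ml_mixed_fit(data, list(covariates), outcome, group)
    model_b = _ml_mixed_fit(data, list(covariates) + list(second_order_names), outcome, group)
    model_c = _ml_mixed_fit(data, list(covariates) + list(all_feature_names), outcome, group)
    return model_a, model_b, model_c


def likelihood_ratio_test(model_small, model_large, alpha: float = 0.05) -> LRTResult:
    """Chi-square likelihood-ratio test between two nested ML fits."""
    small_names = set(model_small.model.exog_names)
    large_names = set(model_large.model.exog_names)
    if not small_names <= large_names:
        raise ContractViolation(
            "models are not nested: smaller model's predictors are not a subset"
        )
    df_diff = len(large_names) - len(small_names)
    stat = 2.0 * (model_large.llf - model_small.llf)
    stat = max(float(stat), 0.0)
    if df_diff == 0:
        return LRTResult("identical", 0, stat, 1.0, float("nan"))
    return LRTResult(
        model_pair=f"{len(large_names)}p vs {len(small_names)}p",
        df_diff=df_diff,
        chi2_stat=stat,
        p=float(stats.chi2.sf(stat, df_diff)),
        critical_value_05=chi2_critical(df_diff, alpha),
    )


def chi2_critical(df: int, alpha: float = 0.05) -> float:
    """Upper-alpha quantile of the chi-square distribution with df degrees of freedom."""
    if df < 1 or not 0.0 < alpha < 1.0:
        raise ValidationError("need df >= 1 and alpha in (0, 1)")
    return float(stats.chi2.ppf(1.0 - alpha, df))
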