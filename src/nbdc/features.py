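"""The 49 Bluetooth features: second-order statistics, multiscale entropy, frequency domain.

Given a preprocessed interval sequence (hourly counts over the valid days of a
14-day questionnaire window), three feature families are computed:

* 16 second-order statistics: max/min/mean/std across days of the daily
  max/min/mean/std, named ``[Second-order]_[Daily]`` (e.g. ``Mean_Max``);
* 24 multiscale sample-entropy values ``MSE_1`` ... ``MSE_24`` (Costa
  coarse-graining, sample entropy with m=2, r=0.2 x SD of the scale-1
  sequence, r held fixed across scales);
* 9 frequency-domain values: periodogram band power sums, band fractions of
  total non-DC power, and normalized spectral entropies in the low
  (0-0.75 cycles/day), middle (0.75-1.25, circadian) and high (>1.25) bands.

All standard deviations use the population (divide-by-n) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractViolation

__all__ = [
    "build_feature_table",
    "EntropyConfig",
    "SpectrumBands",
    "SECOND_ORDER_NAMES",
    "MSE_NAMES",
    "FD_NAMES",
    "FEATURE_NAMES",
    "daily_statistics",
    "second_order_features",
    "coarse_grain",
    "sample_entropy",
    "multiscale_entropy",
    "power_spectrum",
    "band_features",
    "extract_features",
]

_DAILY = ("Max", "Min", "Std", "Mean")
_SECOND = ("Max", "Min", "Mean", "Std")

SECOND_ORDER_NAMES = tuple(f"{so}_{d}" for d in _DAILY for so in _SECOND)
MSE_NAMES = tuple(f"MSE_{tau}" for tau in range(1, 25))
FD_NAMES = (
    "LF_sum", "MF_sum", "HF_sum",
    "LF_pct", "MF_pct", "HF_pct",
    "LF_se", "MF_se", "HF_se",
)
FEATURE_NAMES = SECOND_ORDER_NAMES + MSE_NAMES + FD_NAMES


@dataclass(frozen=True)
class EntropyConfig:
    """Sample-entropy parameters: template length m, tolerance r as a fraction
    of the scale-1 SD, and the largest coarse-graining scale."""

    m: int = 2
    r_fraction: float = 0.2
    max_scale: int = 24

    def __post_init__(self) -> None:
        if self.m < 1 or self.r_fraction <= 0 or self.max_scale < 1:
            raise ContractViolation("invalid entropy configuration")


@dataclass(frozen=True)
class SpectrumBands:
    """Band edges in cycles/day; half-open bins (lo, hi]."""

    lf_hi: float = 0.75
    mf_hi: float = 1.25

    def masks(self, freqs: np.ndarray) -> dict[str, np.ndarray]:
        return {
            "LF": (freqs > 0) & (freqs <= self.lf_hi),
            "MF": (freqs > self.lf_hi) & (freqs <= self.mf_hi),
            "HF": freqs > self.mf_hi,
        }


# ---------------------------------------------------------------------------
# second-order statistics


def daily_statistics(sequence: np.ndarray) -> np.ndarray:
    """Per-day (max, min, std, mean) over each day's 24 hourly values.

    Returns an array of shape (n_days, 4) in the column order Max, Min, Std,
    Mean; std is the population SD.
    """
    x = np.asarray(sequence, dtype=float)
    if x.size == 0 or x.size % 24 != 0:
        raise ContractViolation("sequence must hold a positive whole number of days")
    days = x.reshape(-1, 24)
    return np.column_stack(
        [days.max(axis=1), days.min(axis=1), days.std(axis=1), days.mean(axis=1)]
    )


def second_order_features(daily: np.ndarray) -> dict[str, float]:
    """The 16 across-day summaries of the four daily statistics."""
    daily = np.asarray(daily, dtype=float)
    if daily.ndim != 2 or daily.shape[1] != 4 or daily.shape[0] < 1:
        raise ContractViolation("expected (n_days, 4) daily statistics")
    out: dict[str, float] = {}
    for j, dname in enumerate(_DAILY):
        col = daily[:, j]
        stats = {"Max": col.max(), "Min": col.min(), "Mean": col.mean(), "Std": col.std()}
        for so in _SECOND:
            out[f"{so}_{dname}"] = float(stats[so])
    return out


# ---------------------------------------------------------------------------
# multiscale entropy


def coarse_grain(sequence: np.ndarray, tau: int) -> np.ndarray:
    """Average non-overlapping blocks of length tau; remainder dropped."""
    x = np.asarray(sequence, dtype=float)
    if tau < 1:
        raise ContractViolation("scale must be >= 1")
    if tau > x.size:
        raise ContractViolation(f"scale {tau} exceeds sequence length {x.size}")
    n = x.size // tau
    return x[: n * tau].reshape(n, tau).mean(axis=1)


def sample_entropy(sequence: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy: -ln(A/B) over Chebyshev template matches.

    B counts pairs of m-length templates within tolerance r (self-matches
    excluded), A the same for (m+1)-length templates; both use the first
    N - m templates so the counts are comparable.  When no matches exist the
    Richman-Moorman upper bound ln((N-m)(N-m-1)/2) is returned so the value
    stays finite.
    """
    x = np.asarray(sequence, dtype=float)
    n = x.size
    if n < m + 2:
        raise ContractViolation(f"need at least m+2={m + 2} points, got {n}")
    if r is None:
        r = 0.2 * x.std()
    if r < 0:
        raise ContractViolation("tolerance r must be nonnegative")

    n_t = n - m
    d = np.abs(x[None, :] - x[:, None])
    dm = d[:n_t, :n_t].copy()
    for k in range(1, m):
        np.maximum(dm, d[k : k + n_t, k : k + n_t], out=dm)
    b = (np.count_nonzero(dm <= r) - n_t) // 2
    np.maximum(dm, d[m : m + n_t, m : m + n_t], out=dm)
    a = (np.count_nonzero(dm <= r) - n_t) // 2
    if a == 0 or b == 0:
        return float(-np.log(2.0 / (n_t * (n_t - 1))))
    return float(-np.log(a / b))


def multiscale_entropy(
    sequence: np.ndarray, config: EntropyConfig = EntropyConfig()
) -> dict[str, float]:
    """Sample entropy of the coarse-grained sequence at scales 1..max_scale.

    The tolerance r is fixed from the SD of the original (scale-1) sequence
    and reused at every scale, the Costa convention.
    """
    x = np.asarray(sequence, dtype=float)
    if x.size < config.max_scale * (config.m + 2):
        raise ContractViolation(
            f"sequence of length {x.size} too short for scale {config.max_scale}"
        )
    r = config.r_fraction * x.std()
    return {
        f"MSE_{tau}": sample_entropy(coarse_grain(x, tau), config.m, r)
        for tau in range(1, config.max_scale + 1)
    }


# ---------------------------------------------------------------------------
# frequency domain


def power_spectrum(sequence: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """One-sided periodogram with the frequency axis in cycles/day.

    The hourly sampling rate puts the Nyquist frequency at 12 cycles/day.
    Power is |DFT|^2 / N with interior bins doubled, so the non-DC total
    equals N x population variance (Parseval).  Returns
    ``(frequencies, power, dc_power)`` with the DC bin excluded from the
    returned arrays and reported separately.
    """
    x = np.asarray(sequence, dtype=float)
    if np.isnan(x).any():
        raise ContractViolation("spectrum input must not contain missing values")
    if x.size < 48:
        raise ContractViolation("need at least 48 hourly values (two days)")
    n = x.size
    spec = np.abs(np.fft.rfft(x)) ** 2 / n
    # zero out bins below the FFT rounding floor so constant (or shifted)
    # inputs report exactly no oscillatory power
    floor = (16 * np.finfo(float).eps) ** 2 * n * max(np.abs(x).max(), 1.0) ** 2
    spec[spec < floor] = 0.0
    freqs = np.fft.rfftfreq(n, d=1.0 / 24.0)  # cycles per day
    one_sided = spec.copy()
    last = n // 2 if n % 2 == 0 else one_sided.size - 1
    one_sided[1:last] *= 2.0
    if n % 2 == 1:
        one_sided[last] *= 2.0
    return freqs[1:], one_sided[1:], float(one_sided[0])


def band_features(
    freqs: np.ndarray, power: np.ndarray, bands: SpectrumBands = SpectrumBands()
) -> dict[str, float]:
    """Band power sums, fractions of total non-DC power, and spectral entropies.

    Spectral entropy is the Shannon entropy of the within-band normalized
    power, divided by log(#bins in band) so it lies in [0, 1] (1 = flat, no
    dominant rhythm).  With zero total power the fractions and entropies are
    undefined and returned as NaN.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    if freqs.size == 0 or freqs.size != power.size:
        raise ContractViolation("frequencies and power must be equal-length, non-empty")
    masks = bands.masks(freqs)
    if any(not m.any() for m in masks.values()):
        raise ContractViolation("every band must contain at least one frequency bin")
    total = power.sum()
    out: dict[str, float] = {}
    for name, mask in masks.items():
        out[f"{name}_sum"] = float(power[mask].sum())
    for name, mask in masks.items():
        out[f"{name}_pct"] = float(out[f"{name}_sum"] / total) if total > 0 else float("nan")
    for name, mask in masks.items():
        bp = power[mask]
        s = bp.sum()
        if s <= 0:
            out[f"{name}_se"] = float("nan")
            continue
        if bp.size == 1:
            out[f"{name}_se"] = 1.0  # single-bin band is trivially flat
            continue
        p = bp / s
        nz = p[p > 0]
        out[f"{name}_se"] = float(-(nz * np.log(nz)).sum() / np.log(bp.size))
    return {k: out[k] for k in FD_NAMES}


# ---------------------------------------------------------------------------
# assembly


def extract_features(
    sequence: np.ndarray,
    entropy: EntropyConfig = EntropyConfig(),
    bands: SpectrumBands = SpectrumBands(),
) -> dict[str, float]:
    """All Bluetooth features of one interval sequence, in stable name order.

    With the default configuration this is the full 49-feature vector
    (16 second-order + 24 MSE + 9 frequency-domain); a smaller
    ``entropy.max_scale`` shortens the MSE block accordingly.
    """
    out = second_order_features(daily_statistics(sequence))
    out.update(multiscale_entropy(sequence, entropy))
    freqs, power, _ = power_spectrum(sequence)
    out.update(band_features(freqs, power, bands))
    names = (
        SECOND_ORDER_NAMES
        + tuple(f"MSE_{t}" for t in range(1, entropy.max_scale + 1))
        + FD_NAMES
    )
    return {k: out[k] for k in names}


def build_feature_table(
    intervals,
    demographics,
    entropy: EntropyConfig = EntropyConfig(),
    bands: SpectrumBands = SpectrumBands(),
):
    """Feature table: one row per retained interval with ids, covariates and features.

    ``intervals`` is a list of preprocessed interval objects (each carrying a
    gap-free sequence); ``demographics`` a frame keyed by participant_id.
    """
    import pandas as pd

    demo = demographics.set_index("participant_id")
    rows = []
    for iv in intervals:
        row = {
            "participant_id": iv.participant_id,
            "questionnaire_date": iv.questionnaire_date,
            "phq8_score": iv.phq8_score,
            "valid_days": iv.valid_days,
        }
        d = demo.loc[iv.participant_id]
        row.update(
            age=float(d["age"]),
            gender=str(d["gender"]),
            education_years=float(d["education_years"]),
        )
        row.update(extract_features(iv.sequence, entropy, bands))
        rows.append(row)
    return pd.DataFrame(rows)
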