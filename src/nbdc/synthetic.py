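"""Synthetic cohort generator for hourly nearby-Bluetooth-device-count (NBDC) studies.

Emulates the design of a longitudinal mobile-sensing depression cohort: each
participant carries a biweekly PHQ-8 trajectory (an AR(1) latent severity
process mapped to the 0-24 score scale) and an hourly NBDC count series whose
log-intensity combines a participant baseline, a 24 h circadian sinusoid, a
weekday term and noise.  Latent severity couples into the count process along
four channels -- overall amount, day-to-day variance, circadian amplitude and
irregularity -- so that rising severity lowers the amount, the variance and
the periodicity of the series while making it more irregular.

All randomness flows from a single cohort seed through
``numpy.random.SeedSequence`` spawning, so a fixed configuration reproduces
byte-identical output files.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "SeverityCoupling",
    "CohortConfig",
    "Participant",
    "generate_phq8_trajectory",
    "generate_participant",
    "generate_nbdc_series",
    "generate_cohort",
    "write_cohort",
]

_HOURS = np.arange(24)
_CIRCADIAN_PEAK_HOUR = 14.0  # afternoon peak of ambient device counts


@dataclass(frozen=True)
class SeverityCoupling:
    """Per-channel effect sizes of latent severity on the count process.

    Each value is the fractional change of the corresponding channel per unit
    of standardized latent severity (dimensionless).  Negative ``amount``,
    ``variance`` and ``circadian_amplitude`` plus positive ``irregularity``
    reproduce the four qualitative changes expected with worsening symptoms.
    """

    amount: float = -0.15
    variance: float = -0.15
    circadian_amplitude: float = -0.25
    irregularity: float = 0.5

    @classmethod
    def null(cls) -> "SeverityCoupling":
        """Coupling with every channel set to zero (null construction)."""
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror a multicenter depression cohort: 316 participants,
    biweekly questionnaires, strong mood autocorrelation, and modest missing
    data at the hour and day level.
    """

    n_participants: int = 316
    followup_days: int = 182
    questionnaire_period_days: int = 14
    seed: int = 0
    start_date: dt.date = dt.date(2019, 1, 1)
    missing_hour_rate: float = 0.10
    missing_day_rate: float = 0.05
    severity_coupling: SeverityCoupling = field(default_factory=SeverityCoupling)
    phq8_ar_coef: float = 0.8
    phq8_noise_sd: float = 2.0
    phq8_population_mean: float = 9.0
    phq8_population_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.followup_days <= 0:
            raise ConfigError("participant and follow-up counts must be positive")
        if self.questionnaire_period_days <= 0:
            raise ConfigError("questionnaire period must be positive")
        for name in ("missing_hour_rate", "missing_day_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        if not 0.0 <= self.phq8_ar_coef <= 1.0:
            raise ConfigError("phq8_ar_coef must lie in [0, 1]")
        if self.phq8_noise_sd < 0:
            raise ConfigError("phq8_noise_sd must be nonnegative")
        if self.followup_days < self.questionnaire_period_days:
            raise ConfigError("follow-up must cover at least one questionnaire period")

    @property
    def n_questionnaires(self) -> int:
        return self.followup_days // self.questionnaire_period_days


@dataclass
class Participant:
    """One synthetic participant: demographics, latent severity and scan traits."""

    participant_id: str
    age: int
    gender: str
    education_years: int
    questionnaire_dates: list[dt.date]
    phq8_scores: np.ndarray  # integers in [0, 24]
    latent_severity_path: np.ndarray  # standardized latent severity per questionnaire
    baseline_log: float  # log mean hourly count
    circadian_amplitude: float  # log-scale sinusoid amplitude
    weekday_effect: float  # additive log-intensity on Mon-Fri
    day_sd: float  # day-level random effect SD (log scale)
    phase_jitter_sd: float  # per-day circadian phase jitter SD (hours)
    hour_noise_sd: float  # hourly log-intensity noise SD
    scan_seed: int  # seed for the participant's count series


def generate_phq8_trajectory(
    config: CohortConfig,
    rng: np.random.Generator,
    start: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one participant's biweekly PHQ-8 trajectory.

    The latent process is AR(1) on the score scale,
    ``x_t = mu + rho * (x_{t-1} - mu) + eps_t``, clipped to [0, 24]; reported
    scores are the latent values rounded to integers.  With ``rho = 1`` and
    zero innovation noise the trajectory is constant at its start value.

    Returns
    -------
    scores, latent : integer scores in [0, 24] and the clipped latent path.
    """
    n_q = config.n_questionnaires
    if n_q < 1:
        raise ConfigError("follow-up too short for a single questionnaire")
    mu = config.phq8_population_mean
    if start is None:
        start = float(np.clip(rng.normal(mu, config.phq8_population_sd), 0.0, 24.0))
    latent = np.empty(n_q)
    x = float(start)
    rho = config.phq8_ar_coef
    for t in range(n_q):
        if t > 0:
            x = mu + rho * (x - mu) + rng.normal(0.0, config.phq8_noise_sd)
        x = float(np.clip(x, 0.0, 24.0))
        latent[t] = x
    scores = np.floor(latent + 0.5).astype(int)
    return scores, latent


def generate_participant(
    config: CohortConfig, index: int, seed_seq: np.random.SeedSequence
) -> Participant:
    """Draw one participant: demographics, PHQ-8 path and scan-process traits."""
    child = seed_seq.spawn(2)
    rng = np.random.default_rng(child[0])
    scan_seed = int(child[1].generate_state(1)[0] % (2**31))

    age = int(np.clip(np.floor(rng.normal(48.0, 14.0) + 0.5), 18, 80))
    gender = "female" if rng.random() < 0.741 else "male"
    education = int(np.clip(np.floor(rng.normal(16.0, 3.5) + 0.5), 6, 26))

    scores, latent = generate_phq8_trajectory(config, rng)
    severity_z = (latent - config.phq8_population_mean) / config.phq8_population_sd

    period = config.questionnaire_period_days
    q_dates = [
        config.start_date + dt.timedelta(days=period * (k + 1))
        for k in range(config.n_questionnaires)
    ]

    return Participant(
        participant_id=f"P{index:04d}",
        age=age,
        gender=gender,
        education_years=education,
        questionnaire_dates=q_dates,
        phq8_scores=scores,
        latent_severity_path=severity_z,
        baseline_log=rng.normal(np.log(4.0), 0.45),
        circadian_amplitude=max(rng.normal(0.9, 0.15), 0.1),
        weekday_effect=rng.normal(0.15, 0.05),
        day_sd=0.25,
        phase_jitter_sd=1.0,
        hour_noise_sd=0.30,
        scan_seed=scan_seed,
    )


def generate_nbdc_series(participant: Participant, config: CohortConfig) -> pd.DataFrame:
    """Simulate the hourly NBDC count series for one participant.

    Counts are Poisson with a log-link intensity: participant baseline +
    day-level random effect + weekday term + circadian sinusoid + hourly
    noise.  Latent severity of the questionnaire window covering each day
    modulates the four channels per ``config.severity_coupling``.  Whole days
    and single hours are then removed at the configured missing rates.

    Returns a frame with ``timestamp`` (hourly, UTC) and ``count`` columns.
    """
    rng = np.random.default_rng(participant.scan_seed)
    c = config.severity_coupling

    last_q = participant.questionnaire_dates[-1]
    n_days = (last_q - config.start_date).days
    day_offsets = np.arange(n_days)
    q_offsets = np.array(
        [(d - config.start_date).days for d in participant.questionnaire_dates]
    )
    # each scan day is modulated by the severity of the questionnaire whose
    # window it falls in: the first questionnaire date strictly after the day
    sev = participant.latent_severity_path[
        np.searchsorted(q_offsets, day_offsets, side="right")
    ]

    base = participant.baseline_log + c.amount * sev
    amp = np.maximum(
        participant.circadian_amplitude * (1.0 + c.circadian_amplitude * sev), 0.0
    )
    day_re = rng.normal(0.0, 1.0, n_days) * np.maximum(
        participant.day_sd * (1.0 + c.variance * sev), 0.0
    )
    phase = rng.normal(0.0, 1.0, n_days) * np.maximum(
        participant.phase_jitter_sd * (1.0 + c.irregularity * sev), 0.0
    )
    noise_sd = np.maximum(
        participant.hour_noise_sd * (1.0 + c.irregularity * sev), 0.02
    )

    dow = (day_offsets + config.start_date.weekday()) % 7
    weekday = np.where(dow < 5, participant.weekday_effect, 0.0)

    log_lam = (
        (base + day_re + weekday)[:, None]
        + amp[:, None]
        * np.cos(2.0 * np.pi * (_HOURS[None, :] - _CIRCADIAN_PEAK_HOUR - phase[:, None]) / 24.0)
        + rng.normal(0.0, 1.0, (n_days, 24)) * noise_sd[:, None]
    )
    counts = rng.poisson(np.exp(log_lam))

    keep_day = rng.random(n_days) >= config.missing_day_rate
    keep_hour = rng.random((n_days, 24)) >= config.missing_hour_rate
    keep = keep_day[:, None] & keep_hour

    start = pd.Timestamp(config.start_date)
    timestamps = start + pd.to_timedelta(
        (day_offsets[:, None] * 24 + _HOURS[None, :]).ravel(), unit="h"
    )
    frame = pd.DataFrame({"timestamp": timestamps, "count": counts.ravel()})
    return frame.loc[keep.ravel()].reset_index(drop=True)


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a full cohort: scan, PHQ-8 and demographics tables.

    Deterministic for a fixed config (including seed).  Raises
    :class:`ConfigError` if participant identifiers collide.
    """
    root = np.random.SeedSequence(config.seed)
    participants = [
        generate_participant(config, i, child)
        for i, child in enumerate(root.spawn(config.n_participants))
    ]
    ids = [p.participant_id for p in participants]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate participant ids generated")

    scan_frames = []
    phq_rows = []
    demo_rows = []
    for p in participants:
        scans = generate_nbdc_series(p, config)
        scans.insert(0, "participant_id", p.participant_id)
        scan_frames.append(scans)
        for date, score in zip(p.questionnaire_dates, p.phq8_scores):
            phq_rows.append((p.participant_id, date, int(score)))
        demo_rows.append((p.participant_id, p.age, p.gender, p.education_years))

    scans_df = pd.concat(scan_frames, ignore_index=True)
    phq8_df = pd.DataFrame(phq_rows, columns=["participant_id", "date", "score"])
    demo_df = pd.DataFrame(
        demo_rows, columns=["participant_id", "age", "gender", "education_years"]
    )
    return scans_df, phq8_df, demo_df


def write_cohort(
    scans: pd.DataFrame,
    phq8: pd.DataFrame,
    demographics: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the three cohort tables as CSV (UTC ISO-8601 timestamps)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "scans": outdir / "scans.csv",
        "phq8": outdir / "phq8.csv",
        "demographics": outdir / "demographics.csv",
    }
    scans = scans.assign(
        timestamp=pd.to_datetime(scans["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    )
    scans.to_csv(paths["scans"], index=False)
    phq8.to_csv(paths["phq8"], index=False)
    demographics.to_csv(paths["demographics"], index=False)
    return paths
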