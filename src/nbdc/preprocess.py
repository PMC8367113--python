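"""Inclusion criteria and interpolation for hourly NBDC scans.

A calendar day is *valid* when it holds at least ``min_hours_per_day``
(default 12) distinct observed clock-hours.  Each questionnaire defines a
window of ``window_days`` (default 14) calendar days strictly before the
questionnaire date; a window is retained when it contains at least
``min_valid_days`` (default 10) valid days.  Missing hours inside valid days
are linearly interpolated (edge gaps take the nearest observed value) and the
valid days are concatenated chronologically into one gap-free sequence of
``24 * valid_days`` values.  Questionnaires on or after the cutoff date
(default 2020-02-01) are excluded.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractViolation, ValidationError

__all__ = [
    "PreprocessSettings",
    "ValidDayMask",
    "PHQ8Interval",
    "SEVERITY_LEVELS",
    "severity_level",
    "mark_valid_days",
    "interpolate_day",
    "build_intervals",
    "intervals_to_frame",
]

SEVERITY_LEVELS = (
    "asymptomatic",
    "mild",
    "moderate",
    "moderately severe",
    "severe",
)


@dataclass(frozen=True)
class PreprocessSettings:
    min_hours_per_day: int = 12
    window_days: int = 14
    min_valid_days: int = 10
    cutoff_date: dt.date = dt.date(2020, 2, 1)


@dataclass(frozen=True)
class ValidDayMask:
    date: dt.date
    observed_hours: int
    is_valid: bool


@dataclass
class PHQ8Interval:
    """A retained questionnaire window with its preprocessed count sequence."""

    participant_id: str
    questionnaire_date: dt.date
    phq8_score: int
    window_days: int
    valid_days: int
    sequence: np.ndarray  # length 24 * valid_days, no missing values
    severity_level: str

    def __post_init__(self) -> None:
        if len(self.sequence) != 24 * self.valid_days:
            raise ContractViolation(
                f"sequence length {len(self.sequence)} != 24 x {self.valid_days}"
            )


def severity_level(phq8_score: int) -> str:
    """Map a PHQ-8 score to its severity bin.

    Bins are half-open: asymptomatic [0,5), mild [5,10), moderate [10,15),
    moderately severe [15,20), severe [20,24].
    """
    score = int(phq8_score)
    if not 0 <= score <= 24:
        raise ValidationError(f"PHQ-8 score {phq8_score} outside [0, 24]")
    return SEVERITY_LEVELS[min(score // 5, 4)]


def _hourly_means(scans: pd.DataFrame) -> pd.Series:
    """Collapse scans to one value per clock-hour slot (mean, rounded half-up)."""
    ts = scans["timestamp"]
    if not pd.api.types.is_datetime64_any_dtype(ts):
        parsed = pd.to_datetime(ts, errors="coerce", utc=True)
        bad = parsed.isna() & ts.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"unparseable timestamp {ts.iloc[row]!r} at scan row {scans.index[row]}"
            )
        ts = parsed.dt.tz_localize(None)
    hours = ts.dt.floor("h")
    means = scans.groupby(hours)["count"].mean()
    return np.floor(means + 0.5)


def mark_valid_days(scans: pd.DataFrame, min_hours: int = 12) -> list[ValidDayMask]:
    """One validity mask per calendar day spanned by the scan series."""
    if scans.empty:
        return []
    hourly = _hourly_means(scans)
    per_day = hourly.groupby(hourly.index.normalize()).size()
    full = pd.date_range(per_day.index.min(), per_day.index.max(), freq="D")
    per_day = per_day.reindex(full, fill_value=0)
    return [
        ValidDayMask(date=day.date(), observed_hours=int(n), is_valid=int(n) >= min_hours)
        for day, n in per_day.items()
    ]


def interpolate_day(values: np.ndarray, min_hours: int = 12) -> np.ndarray:
    """Fill missing hours of one valid day (24 slots, NaN = missing).

    Interior gaps are filled linearly between the nearest observed neighbours;
    leading/trailing gaps take the nearest observed value.  Observed values
    pass through unchanged.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (24,):
        raise ContractViolation("interpolate_day expects 24 hourly slots")
    observed = ~np.isnan(values)
    if observed.sum() < min_hours:
        raise ContractViolation(
            f"day has {int(observed.sum())} observed hours (< {min_hours}); not a valid day"
        )
    if observed.all():
        return values.copy()
    idx = np.arange(24)
    return np.interp(idx, idx[observed], values[observed])


def build_intervals(
    scans: pd.DataFrame,
    phq8: pd.DataFrame,
    demographics: pd.DataFrame,
    settings: PreprocessSettings = PreprocessSettings(),
) -> tuple[list[PHQ8Interval], pd.DataFrame]:
    """Apply the inclusion criteria and produce retained intervals + rejection log.

    Each questionnaire record yields either a retained :class:`PHQ8Interval`
    (valid days interpolated and concatenated chronologically) or a rejection
    log row naming the failed criterion (``after_cutoff``,
    ``no_scans_in_window`` or ``too_few_valid_days``).
    """
    if (phq8["score"] < 0).any() or (phq8["score"] > 24).any():
        bad = phq8.loc[(phq8["score"] < 0) | (phq8["score"] > 24)].index[0]
        raise ValidationError(f"PHQ-8 score outside [0, 24] at row {bad}")

    known = set(demographics["participant_id"])
    intervals: list[PHQ8Interval] = []
    rejections: list[tuple[str, dt.date, str]] = []

    scans_by_pid = dict(tuple(scans.groupby("participant_id", sort=False)))
    for pid, group in phq8.groupby("participant_id", sort=False):
        if pid not in known:
            for q in group.itertuples():
                rejections.append((pid, _as_date(q.date), "missing_demographics"))
            continue
        pscans = scans_by_pid.get(pid)
        hourly = _hourly_means(pscans) if pscans is not None and not pscans.empty else None
        for q in group.itertuples():
            qdate = _as_date(q.date)
            if qdate >= settings.cutoff_date:
                rejections.append((pid, qdate, "after_cutoff"))
                continue
            if hourly is None:
                rejections.append((pid, qdate, "no_scans_in_window"))
                continue
            w_end = pd.Timestamp(qdate)  # exclusive: window is [qdate - W, qdate)
            w_start = w_end - pd.Timedelta(days=settings.window_days)
            win = hourly.loc[(hourly.index >= w_start) & (hourly.index < w_end)]
            if win.empty:
                rejections.append((pid, qdate, "no_scans_in_window"))
                continue
            days = []
            for day, vals in win.groupby(win.index.normalize()):
                if len(vals) >= settings.min_hours_per_day:
                    slot = np.full(24, np.nan)
                    slot[vals.index.hour] = vals.to_numpy(dtype=float)
                    days.append((day, interpolate_day(slot, settings.min_hours_per_day)))
            if len(days) < settings.min_valid_days:
                rejections.append((pid, qdate, "too_few_valid_days"))
                continue
            days.sort(key=lambda kv: kv[0])
            sequence = np.concatenate([d for _, d in days])
            intervals.append(
                PHQ8Interval(
                    participant_id=pid,
                    questionnaire_date=qdate,
                    phq8_score=int(q.score),
                    window_days=settings.window_days,
                    valid_days=len(days),
                    sequence=sequence,
                    severity_level=severity_level(int(q.score)),
                )
            )

    log = pd.DataFrame(rejections, columns=["participant_id", "questionnaire_date", "reason"])
    return intervals, log


def intervals_to_frame(intervals: list[PHQ8Interval]) -> pd.DataFrame:
    """Metadata table with one row per retained interval."""
    return pd.DataFrame(
        {
            "participant_id": [iv.participant_id for iv in intervals],
            "questionnaire_date": [iv.questionnaire_date for iv in intervals],
            "phq8_score": [iv.phq8_score for iv in intervals],
            "valid_days": [iv.valid_days for iv in intervals],
            "severity_level": [iv.severity_level for iv in intervals],
        }
    )


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return pd.Timestamp(value).date()
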