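"""Table I/O, configuration and the end-to-end pipeline runner.

All interchange is CSV (UTF-8, ISO-8601 timestamps).  Input tables are
schema-validated on read with row-level error reporting; every pipeline run
writes a manifest recording the resolved configuration, seed and input
checksums so any output is regenerable bit-identically.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, features, prediction, preprocess, synthetic
from .errors import ValidationError

__all__ = [
    "RunConfig",
    "read_scans",
    "read_phq8",
    "read_demographics",
    "read_tables",
    "run_pipeline",
]

log = logging.getLogger("nbdc")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (YAML round-trippable)."""

    outdir: str = "results/run"
    scans: str | None = None
    phq8: str | None = None
    demographics: str | None = None
    simulate: bool = True
    seed: int = 0
    n_participants: int = 60
    followup_days: int = 126
    min_hours_per_day: int = 12
    min_valid_days: int = 10
    window_days: int = 14
    cutoff_date: str = "2020-02-01"
    entropy_m: int = 2
    entropy_r_fraction: float = 0.2
    entropy_max_scale: int = 24
    min_intervals: int = 3
    min_score_range: int = 5
    cv_scheme: str = "lao"
    draws: int = 300
    tune: int = 300
    chains: int = 2
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def preprocess_settings(self) -> preprocess.PreprocessSettings:
        return preprocess.PreprocessSettings(
            min_hours_per_day=self.min_hours_per_day,
            window_days=self.window_days,
            min_valid_days=self.min_valid_days,
            cutoff_date=dt.date.fromisoformat(self.cutoff_date),
        )

    def entropy_config(self) -> features.EntropyConfig:
        return features.EntropyConfig(
            m=self.entropy_m,
            r_fraction=self.entropy_r_fraction,
            max_scale=self.entropy_max_scale,
        )


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{name} table is missing required column(s) {missing}")


def read_scans(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("participant_id", "timestamp", "count"), "scans")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    bad = ts.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: unparseable timestamp {df['timestamp'].iloc[row]!r} at row {row + 2}"
        )
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts < 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: invalid count {df['count'].iloc[row]!r} at row {row + 2}"
        )
    return pd.DataFrame(
        {
            "participant_id": df["participant_id"].astype(str),
            "timestamp": ts.dt.tz_localize(None),
            "count": counts.astype(float),
        }
    )


def read_phq8(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("participant_id", "date", "score"), "phq8")
    dates = pd.to_datetime(df["date"], errors="coerce")
    if dates.isna().any():
        row = int(np.flatnonzero(dates.isna().to_numpy())[0])
        raise ValidationError(f"{path}: unparseable date at row {row + 2}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    bad = scores.isna() | (scores < 0) | (scores > 24)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: PHQ-8 score {df['score'].iloc[row]!r} outside [0, 24] at row {row + 2}"
        )
    return pd.DataFrame(
        {
            "participant_id": df["participant_id"].astype(str),
            "date": dates.dt.date,
            "score": scores.astype(int),
        }
    )


def read_demographics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(
        df, ("participant_id", "age", "gender", "education_years"), "demographics"
    )
    for col in ("age", "education_years"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals < 0).any():
            row = int(np.flatnonzero((vals.isna() | (vals < 0)).to_numpy())[0])
            raise ValidationError(f"{path}: invalid {col} at row {row + 2}")
        df[col] = vals
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def read_tables(
    scans_path: str | Path, phq8_path: str | Path, demo_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and validate the three cohort tables."""
    return read_scans(scans_path), read_phq8(phq8_path), read_demographics(demo_path)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute simulate (optional) -> preprocess -> features -> associate -> predict.

    Writes every stage's artifacts plus a manifest (resolved config, seed,
    input checksums, stage timings and record counts) to ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "config": dataclasses.asdict(config)}

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                **counts,
            }
            log.info("stage %s done in %.2fs %s", name, time.perf_counter() - t0, counts)

        return done

    if config.simulate:
        done = stage("simulate")
        cohort_cfg = synthetic.CohortConfig(
            n_participants=config.n_participants,
            followup_days=config.followup_days,
            seed=config.seed,
        )
        scans, phq8, demo = synthetic.generate_cohort(cohort_cfg)
        paths = synthetic.write_cohort(scans, phq8, demo, outdir / "cohort")
        done(scan_rows=len(scans), phq8_rows=len(phq8), participants=len(demo))
    else:
        if not (config.scans and config.phq8 and config.demographics):
            raise ValidationError("simulate=false requires scans/phq8/demographics paths")
        paths = {
            "scans": Path(config.scans),
            "phq8": Path(config.phq8),
            "demographics": Path(config.demographics),
        }
        scans, phq8, demo = read_tables(paths["scans"], paths["phq8"], paths["demographics"])
    manifest["inputs"] = {k: {"path": str(p), "sha256": _checksum(Path(p))} for k, p in paths.items()}

    done = stage("preprocess")
    if scans.empty:
        raise ValidationError("preprocess: scan table is empty; nothing to analyse")
    intervals, rejections = preprocess.build_intervals(
        scans, phq8, demo, config.preprocess_settings()
    )
    preprocess.intervals_to_frame(intervals).to_csv(outdir / "intervals.csv", index=False)
    rejections.to_csv(outdir / "rejections.csv", index=False)
    done(retained=len(intervals), rejected=len(rejections))

    done = stage("features")
    table = features.build_feature_table(intervals, demo, config.entropy_config())
    table.to_csv(outdir / "features.csv", index=False)
    done(rows=len(table))

    done = stage("associate")
    names = [c for c in features.FEATURE_NAMES if c in table.columns]
    assoc = association.associate_all(table, names)
    assoc.to_csv(outdir / "associations.csv", index=False)
    a, b, c_ = association.fit_nested_models(
        table, list(features.SECOND_ORDER_NAMES), names
    )
    lrt = pd.DataFrame(
        [
            dataclasses.asdict(association.likelihood_ratio_test(a, b)),
            dataclasses.asdict(association.likelihood_ratio_test(a, c_)),
            dataclasses.asdict(association.likelihood_ratio_test(b, c_)),
        ]
    )
    lrt.insert(0, "comparison", ["B vs A", "C vs A", "C vs B"])
    lrt.to_csv(outdir / "lrt.csv", index=False)
    done(significant=int((assoc["p_adjusted"] < config.alpha).sum()))

    done = stage("predict")
    table = prediction.add_last_phq8(table)
    subset = prediction.select_prediction_subset(
        table, config.min_intervals, config.min_score_range
    )
    sub = table[table["participant_id"].isin(subset)].reset_index(drop=True)
    metrics_rows = []
    if len(subset) >= 2:
        sub = association.encode_covariates(sub)
        plan = (
            prediction.lao_splits(sub)
            if config.cv_scheme.lower() == "lao"
            else prediction.loo_splits(sub)
        )
        prediction.validate_plan(plan, sub)
        for label, feats in (
            ("full", tuple(names)),
            ("baseline", ()),
        ):
            spec = prediction.HierModelSpec(
                feature_names=feats,
                draws=config.draws,
                tune=config.tune,
                chains=config.chains,
                seed=config.seed,
            )
            preds, metrics = prediction.run_cv(sub, plan, spec)
            preds.to_csv(outdir / f"predictions_{label}.csv", index=False)
            metrics_rows.append(
                {
                    "scheme": plan.scheme,
                    "model": label,
                    "r2": metrics.r2,
                    "rmse": metrics.rmse,
                    "n_test": metrics.n_test,
                }
            )
    pd.DataFrame(metrics_rows).to_csv(outdir / "metrics.csv", index=False)
    done(subset_participants=len(subset))

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
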