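import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from nbdc.features import build_feature_table
from nbdc.preprocess import build_intervals
from nbdc.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact coupled cohort shared across read-only tests."""
    cfg = CohortConfig(n_participants=10, followup_days=98, seed=101)
    scans, phq8, demo = generate_cohort(cfg)
    return cfg, scans, phq8, demo


@pytest.fixture(scope="session")
def small_intervals(small_cohort):
    _, scans, phq8, demo = small_cohort
    intervals, rejections = build_intervals(scans, phq8, demo)
    return intervals, rejections


@pytest.fixture(scope="session")
def small_feature_table(small_cohort, small_intervals):
    _, _, _, demo = small_cohort
    intervals, _ = small_intervals
    return build_feature_table(intervals, demo)


def make_interval_frame(t_per_participant: dict[str, int]) -> pd.DataFrame:
    """Light interval-metadata frame (no sequences) for CV-plan tests."""
    rows = []
    rng = np.random.default_rng(0)
    for pid, t in t_per_participant.items():
        scores = rng.integers(0, 25, size=t)
        for k in range(t):
            rows.append(
                {
                    "participant_id": pid,
                    "questionnaire_date": pd.Timestamp("2019-01-01")
                    + pd.Timedelta(days=14 * (k + 1)),
                    "phq8_score": int(scores[k]),
                }
            )
    return pd.DataFrame(rows)
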