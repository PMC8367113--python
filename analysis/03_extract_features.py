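#!/usr/bin/env python
"""Extract the 49 Bluetooth features for every retained interval.

16 second-order statistics of the daily max/min/mean/std, multiscale sample
entropy at scales 1-24, and periodogram band powers / fractions / spectral
entropies in the low (<0.75), middle (0.75-1.25, circadian) and high
(>1.25 cycles/day) bands.  Writes results/features.csv.
"""

from pathlib import Path

from nbdc.features import FEATURE_NAMES, build_feature_table
from nbdc.io import read_tables
from nbdc.preprocess import build_intervals

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = ROOT / "cohort"
    tables = read_tables(
        cohort / "scans.csv", cohort / "phq8.csv", cohort / "demographics.csv"
    )
    intervals, _ = build_intervals(*tables)
    table = build_feature_table(intervals, tables[2])
    table.to_csv(ROOT / "features.csv", index=False)
    print(f"extracted {len(FEATURE_NAMES)} features x {len(table)} intervals")
    summary = table[["Mean_Mean", "Std_Std", "MSE_1", "MSE_12", "MF_sum", "MF_pct"]]
    print(summary.describe().loc[["mean", "std", "min", "max"]].round(3).to_string())


if __name__ == "__main__":
    main()
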