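#!/usr/bin/env python
"""Apply the inclusion criteria to the simulated cohort.

A day is valid with >= 12 observed hours; a questionnaire window (the 14 days
before the PHQ-8 date) is retained with >= 10 valid days.  Missing hours in
valid days are linearly interpolated.  Writes the interval metadata and the
rejection log under results/.
"""

from pathlib import Path

from nbdc.io import read_tables
from nbdc.preprocess import build_intervals, intervals_to_frame

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = ROOT / "cohort"
    tables = read_tables(
        cohort / "scans.csv", cohort / "phq8.csv", cohort / "demographics.csv"
    )
    intervals, rejections = build_intervals(*tables)
    meta = intervals_to_frame(intervals)
    meta.to_csv(ROOT / "intervals.csv", index=False)
    rejections.to_csv(ROOT / "rejections.csv", index=False)
    total = len(tables[1])
    print(f"retained {len(meta)}/{total} questionnaire intervals "
          f"({len(meta) / total:.1%}); {len(rejections)} rejected")
    if len(rejections):
        print(rejections["reason"].value_counts().to_string())
    print("valid-day distribution:")
    print(meta["valid_days"].value_counts().sort_index().to_string())
    print("severity mix:")
    print(meta["severity_level"].value_counts().to_string())


if __name__ == "__main__":
    main()
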