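#!/usr/bin/env python
"""Screen every Bluetooth feature against the PHQ-8 score.

Each feature enters its own linear mixed-effects model (random participant
intercept; age, gender and education as covariates); p-values are
Benjamini-Hochberg adjusted across the 49 tests.  The nested ladder
(demographics / + second-order / + all features) is then compared with
likelihood-ratio tests.  Writes results/associations.csv and results/lrt.csv.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from nbdc.association import associate_all, fit_nested_models, likelihood_ratio_test
from nbdc.features import FEATURE_NAMES, SECOND_ORDER_NAMES

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = pd.read_csv(ROOT / "features.csv")
    res = associate_all(table, list(FEATURE_NAMES))
    res.to_csv(ROOT / "associations.csv", index=False)
    sig = res[res["p_adjusted"] < 0.05].sort_values("p_adjusted")
    print(f"{len(sig)}/49 features significant after FDR correction; strongest:")
    cols = ["feature_name", "estimate", "se", "z", "p_adjusted"]
    print(sig[cols].head(10).round(4).to_string(index=False))
    direction = {
        "amount (Mean_Mean)": res.set_index("feature_name").loc["Mean_Mean", "z"],
        "variance (Std_Std)": res.set_index("feature_name").loc["Std_Std", "z"],
        "circadian power (MF_sum)": res.set_index("feature_name").loc["MF_sum", "z"],
        "irregularity (MSE_1)": res.set_index("feature_name").loc["MSE_1", "z"],
    }
    print("directions of effect (z):",
          {k: round(v, 2) for k, v in direction.items()})

    a, b, c = fit_nested_models(table, list(SECOND_ORDER_NAMES), list(FEATURE_NAMES))
    rows = []
    for label, pair in (("B vs A", (a, b)), ("C vs A", (a, c)), ("C vs B", (b, c))):
        r = dataclasses.asdict(likelihood_ratio_test(*pair))
        r["comparison"] = label
        rows.append(r)
    lrt = pd.DataFrame(rows)
    lrt.to_csv(ROOT / "lrt.csv", index=False)
    print("\nnested model ladder (likelihood-ratio tests):")
    print(lrt[["comparison", "df_diff", "chi2_stat", "p", "critical_value_05"]]
          .round(3).to_string(index=False))


if __name__ == "__main__":
    main()
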