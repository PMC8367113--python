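#!/usr/bin/env python
"""Predict PHQ-8 scores under both time-series cross-validation schemes.

Participants with >= 3 retained intervals and a score range >= 5 enter the
prediction subset.  The full hierarchical Bayesian model (49 features +
demographics + last observed score, partial pooling per participant) is
compared with the last-score + demographics baseline under leave-all-out
(LAO) and leave-one-out (LOO) rolling-origin CV.  Writes results/metrics.csv
and per-fold predictions.
"""

from pathlib import Path

import pandas as pd

from nbdc.association import encode_covariates
from nbdc.features import FEATURE_NAMES
from nbdc.prediction import (
    HierModelSpec,
    add_last_phq8,
    lao_splits,
    loo_splits,
    run_cv,
    select_prediction_subset,
    validate_plan,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def main() -> None:
    table = encode_covariates(pd.read_csv(ROOT / "features.csv"))
    table = add_last_phq8(table)
    subset = select_prediction_subset(table)
    sub = table[table["participant_id"].isin(subset)].reset_index(drop=True)
    print(f"prediction subset: {len(subset)} participants, {len(sub)} intervals")

    rows = []
    for scheme, splitter in (("LAO", lao_splits), ("LOO", loo_splits)):
        plan = splitter(sub)
        validate_plan(plan, sub)
        print(f"\n{scheme}: {len(plan.folds)} folds (T={plan.T}, J={plan.J})")
        for model, feats in (("full", tuple(FEATURE_NAMES)), ("baseline", ())):
            spec = HierModelSpec(
                feature_names=feats, draws=500, tune=500, chains=2, seed=SEED
            )
            preds, metrics = run_cv(sub, plan, spec)
            preds.to_csv(ROOT / f"predictions_{scheme.lower()}_{model}.csv", index=False)
            rows.append(
                {"scheme": scheme, "model": model, "r2": metrics.r2,
                 "rmse": metrics.rmse, "n_test": metrics.n_test}
            )
            print(f"  {model:8s} R2={metrics.r2:.3f} RMSE={metrics.rmse:.3f} "
                  f"(n={metrics.n_test})")
    out = pd.DataFrame(rows)
    out.to_csv(ROOT / "metrics.csv", index=False)
    lao = out[out["scheme"] == "LAO"].set_index("model")
    gain = lao.loc["full", "r2"] - lao.loc["baseline", "r2"]
    print(f"\nBluetooth features add {gain:.3f} to pooled LAO R2 over the baseline")


if __name__ == "__main__":
    main()
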