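#!/usr/bin/env python
"""External validation: train on study 1, predict the validation cohort.

Both studies are restricted to their 52 shared identified metabolites;
the training set is balanced to nine observations per group before
fitting one OPLS-DA model, which then predicts every validation sample.
Writes per-sample predictions, metrics and the serialized model to
results/validation/.
"""

import json
from pathlib import Path

import pandas as pd

from metadx import Group, external_validate, read_feature_table
from metadx.opls import save_model

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20110208


def main():
    d = ROOT / "data"
    train, train_meta = read_feature_table(
        d / "study1_intensities.csv", d / "study1_samples.csv",
        annotations_path=d / "study1_metabolites.csv",
    )
    test, test_meta = read_feature_table(
        d / "validation_intensities.csv", d / "validation_samples.csv",
        annotations_path=d / "validation_metabolites.csv",
    )
    keep = [m.sample_id for m in train_meta if m.group in (Group.RA, Group.CONTROL)]
    res = external_validate(
        train.subset_samples(keep),
        [m for m in train_meta if m.sample_id in set(keep)],
        test, test_meta, balance=9, seed=SEED,
    )
    print(f"shared identified metabolites: {len(res.shared_identified)}")
    print(f"training set: {len(res.train_sample_ids)} samples (9 per group)")
    print(f"validation: sensitivity {res.sensitivity:.0%}, specificity {res.specificity:.0%}")

    out = ROOT / "validation"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "sample_id": res.test_sample_ids,
        "y_hat": res.y_hat,
        "predicted_class": [g.value for g in res.predicted_class],
    }).to_csv(out / "predictions.csv", index=False, float_format="%.6g")
    save_model(res.model, out / "model.json")
    with open(out / "metrics.json", "w") as fh:
        json.dump({
            "n_shared_identified": len(res.shared_identified),
            "sensitivity": res.sensitivity,
            "specificity": res.specificity,
            "confusion": {"TP": res.confusion[0], "FP": res.confusion[1],
                          "TN": res.confusion[2], "FN": res.confusion[3]},
        }, fh, indent=1)


if __name__ == "__main__":
    main()
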