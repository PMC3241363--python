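#!/usr/bin/env python
"""Sevenfold cross-validated OPLS-DA diagnosis on the discovery cohort.

Fits separate models for RA vs healthy controls and RA vs PsoA, each
tested by sevenfold cross-validation (preprocessing refit per fold),
plus an identified-metabolites-only variant of the RA-vs-control model.
Writes per-sample out-of-fold predictions and a metrics table to
results/crossval/.
"""

import json
from pathlib import Path

import pandas as pd

from metadx import Group, crossval_predict, read_feature_table, select_identified

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20110208


def _load():
    d = ROOT / "data"
    return read_feature_table(
        d / "study1_intensities.csv", d / "study1_samples.csv",
        annotations_path=d / "study1_metabolites.csv",
    )


def _run(table, meta, groups, tag):
    keep = [m.sample_id for m in meta if m.group in groups]
    sub = table.subset_samples(keep)
    sub_meta = [m for m in meta if m.sample_id in set(keep)]
    res = crossval_predict(sub, sub_meta, k=7, n_orth=1, seed=SEED)
    print(f"{tag}: sensitivity {res.sensitivity:.0%}, specificity {res.specificity:.0%}, "
          f"Q2 {res.q2:.2f}")
    out = ROOT / "crossval"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "sample_id": res.sample_ids,
        "fold": res.fold_of_sample,
        "y_hat": res.y_hat,
        "predicted_class": [g.value for g in res.predicted_class],
    }).to_csv(out / f"predictions_{tag}.csv", index=False, float_format="%.6g")
    return {
        "sensitivity": res.sensitivity,
        "specificity": res.specificity,
        "q2": res.q2,
        "confusion": {"TP": res.confusion[0], "FP": res.confusion[1],
                      "TN": res.confusion[2], "FN": res.confusion[3]},
    }


def main():
    table, meta = _load()
    metrics = {
        "ra_vs_control": _run(table, meta, (Group.RA, Group.CONTROL), "ra_vs_control"),
        "ra_vs_psoa": _run(table, meta, (Group.RA, Group.PSOA), "ra_vs_psoa"),
        "ra_vs_control_identified_only": _run(
            select_identified(table), meta, (Group.RA, Group.CONTROL), "identified_only"
        ),
    }
    with open(ROOT / "crossval" / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=1)


if __name__ == "__main__":
    main()
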