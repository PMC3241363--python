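#!/usr/bin/env python
"""Metabolite-level interpretation of the discovery cohort.

For each contrast (RA vs control, RA vs PsoA): per-metabolite
pooled-variance t-tests (uncorrected, identified metabolites only),
the increased/decreased differential table, p(corr) ranking from the
fitted OPLS-DA model, and the z-score heat map (reference-group mean,
truncated to +/-2, columns sorted by p(corr)). Outputs go to
results/report/.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from metadx import (
    Group,
    build_heatmap,
    read_feature_table,
    render_table1,
    select_identified,
    ttest_table,
)
from metadx.datamodel import groups_for
from metadx.interpret import table1_text
from metadx.opls import fit_oplsda

ROOT = Path(__file__).resolve().parents[1] / "results"


def _contrast(table, meta, positive, reference, tag, out):
    keep = [m.sample_id for m in meta if m.group in (positive, reference)]
    sub = select_identified(table.subset_samples(keep))
    sub_meta = [m for m in meta if m.sample_id in set(keep)]
    model = fit_oplsda(sub.intensities, groups_for(sub, sub_meta), positive=positive, n_orth=1)

    reports = ttest_table(sub, sub_meta, group_a=positive, group_b=reference,
                          model=model, identified_only=False)
    pd.DataFrame([dataclasses.asdict(r) for r in reports]).to_csv(
        out / f"metabolite_report_{tag}.csv", index=False, float_format="%.6g")

    rendered = render_table1(reports)
    (out / f"differential_{tag}.txt").write_text(
        table1_text(rendered, title=f"Differential metabolites, {tag}"))
    with open(out / f"differential_{tag}.json", "w") as fh:
        json.dump(rendered, fh, indent=1)

    heat = build_heatmap(sub, sub_meta, model, reference=reference, limit=2.0)
    hm = pd.DataFrame(heat.z, index=heat.sample_ids, columns=heat.metabolite_ids)
    hm.index.name = "sample_id"
    hm.to_csv(out / f"heatmap_{tag}.csv", float_format="%.4g")

    print(f"{tag}: {len(rendered['increased'])} increased, "
          f"{len(rendered['decreased'])} decreased (p < 0.05, uncorrected)")
    top = sorted(reports, key=lambda r: -abs(r.pcorr))[:5]
    print("  strongest by |p(corr)|: " + ", ".join(
        f"{r.metabolite_id} ({r.pcorr:+.2f})" for r in top))


def main():
    d = ROOT / "data"
    table, meta = read_feature_table(
        d / "study1_intensities.csv", d / "study1_samples.csv",
        annotations_path=d / "study1_metabolites.csv",
    )
    out = ROOT / "report"
    out.mkdir(parents=True, exist_ok=True)
    _contrast(table, meta, Group.RA, Group.CONTROL, "ra_vs_control", out)
    _contrast(table, meta, Group.RA, Group.PSOA, "ra_vs_psoa", out)


if __name__ == "__main__":
    main()
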