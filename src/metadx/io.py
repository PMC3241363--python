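"""Delimited-text readers and writers for feature tables and metadata.

Layout on disk (CSV or TSV, autodetected from the file extension):

* intensities: header row of metabolite ids, first column sample ids;
* sample metadata: columns ``sample_id, group, study`` plus free
  covariate columns, keyed by sample id;
* metabolite annotations (sidecar file): columns
  ``metabolite_id, identified, platform``.

Intensities are written with 17 significant digits so a write/read
round-trip reproduces them bit-exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import FeatureTable, Group, SampleMeta, check_meta

_TRUE = {"true", "1", "yes", "y", "t"}


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt", ".tab")) else ","


def read_feature_table(
    path,
    meta_path,
    annotations_path=None,
    sep: Optional[str] = None,
):
    """Read an intensity table plus sample metadata (and annotations).

    Unparseable numeric cells become missing values (NaN). Sample order
    is preserved from the intensity file. Every sample must have exactly
    one metadata row; violations raise naming the offending sample.

    Returns
    -------
    (FeatureTable, list of SampleMeta)
    """
    df = pd.read_csv(path, sep=sep or _sep(path), index_col=0, dtype=str)
    sample_ids = [str(s) for s in df.index]
    metabolite_ids = [str(c) for c in df.columns]

    def _cell(v):
        # Python's float() is correctly rounded (unlike pandas' fast parser),
        # so written values round-trip bit-exactly; anything unparseable is NaN
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    intensities = np.array(
        [[_cell(v) for v in row] for row in df.to_numpy()], dtype=float
    ).reshape(len(sample_ids), len(metabolite_ids))

    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep=sep or _sep(annotations_path), dtype=str)
        ann = ann.set_index("metabolite_id")
        missing = [m for m in metabolite_ids if m not in ann.index]
        if missing:
            raise ValueError(f"metabolites without annotation rows: {missing[:5]}")
        identified = np.array(
            [str(ann.loc[m, "identified"]).strip().casefold() in _TRUE for m in metabolite_ids]
        )
        platform = [str(ann.loc[m, "platform"]) for m in metabolite_ids]
    else:
        identified = np.zeros(len(metabolite_ids), dtype=bool)
        platform = ["NA"] * len(metabolite_ids)

    table = FeatureTable(
        sample_ids=sample_ids,
        metabolite_ids=metabolite_ids,
        intensities=intensities,
        identified=identified,
        platform=platform,
    )

    mdf = pd.read_csv(meta_path, sep=sep or _sep(meta_path), dtype=str)
    known = {"sample_id", "group", "study"}
    meta = []
    for _, row in mdf.iterrows():
        cov = {k: row[k] for k in mdf.columns if k not in known and pd.notna(row[k])}
        meta.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                group=Group.parse(row["group"]),
                study=str(row.get("study", "") or ""),
                covariates=cov,
            )
        )
    check_meta(table, meta)
    return table, meta


def write_feature_table(
    table: FeatureTable,
    meta: Sequence[SampleMeta],
    out_dir,
    prefix: str = "",
    sep: str = ",",
) -> dict:
    """Write intensities, metadata and annotations as delimited text.

    Returns a dict of the three paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".tsv" if sep == "\t" else ".csv"
    paths = {
        "intensities": out_dir / f"{prefix}intensities{ext}",
        "samples": out_dir / f"{prefix}samples{ext}",
        "metabolites": out_dir / f"{prefix}metabolites{ext}",
    }

    df = pd.DataFrame(table.intensities, index=table.sample_ids, columns=table.metabolite_ids)
    df.index.name = "sample_id"
    df.to_csv(paths["intensities"], sep=sep, float_format="%.17g")

    cov_keys = sorted({k for m in meta for k in m.covariates})
    rows = []
    for m in meta:
        row = {"sample_id": m.sample_id, "group": m.group.value, "study": m.study}
        row.update({k: m.covariates.get(k, "") for k in cov_keys})
        rows.append(row)
    pd.DataFrame(rows).to_csv(paths["samples"], sep=sep, index=False)

    ann = pd.DataFrame(
        {
            "metabolite_id": table.metabolite_ids,
            "identified": table.identified,
            "platform": table.platform,
        }
    )
    ann.to_csv(paths["metabolites"], sep=sep, index=False)
    return paths
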