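"""Core containers: feature tables, sample metadata, cross-study pairs.

Orientation is fixed across the codebase: samples in rows, metabolites in
columns. Missing intensities are carried explicitly as NaN (never zero);
imputation happens in :mod:`metadx.preprocess`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class Group(str, Enum):
    """Clinical group of a serum sample."""

    RA = "RA"
    CONTROL = "control"
    PSOA = "PsoA"

    @classmethod
    def parse(cls, value: "Group | str") -> "Group":
        if isinstance(value, Group):
            return value
        key = str(value).strip().casefold()
        aliases = {
            "ra": cls.RA,
            "control": cls.CONTROL,
            "ctrl": cls.CONTROL,
            "healthy": cls.CONTROL,
            "psoa": cls.PSOA,
        }
        if key not in aliases:
            raise ValueError(f"unknown group label: {value!r}")
        return aliases[key]


@dataclass
class SampleMeta:
    """Per-sample metadata: group label, study id, optional covariates."""

    sample_id: str
    group: Group
    study: str = ""
    covariates: dict = field(default_factory=dict)


def _match_key(metabolite_id: str) -> str:
    """Cross-study matching key: trimmed, case-folded exact name."""
    return metabolite_id.strip().casefold()


@dataclass
class FeatureTable:
    """Samples x metabolites semiquantitative intensity matrix.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row.
    metabolite_ids
        Unique metabolite identifiers, one per column.
    intensities
        Nonnegative intensities, NaN for missing, shape
        ``(len(sample_ids), len(metabolite_ids))``.
    identified
        Boolean flag per metabolite: True if the feature carries a
        positive chemical identification.
    platform
        Analytical platform tag per metabolite (e.g. ``"GC"``/``"LC"``).
    """

    sample_ids: list
    metabolite_ids: list
    intensities: np.ndarray
    identified: np.ndarray
    platform: list

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.metabolite_ids = [str(m) for m in self.metabolite_ids]
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.identified = np.asarray(self.identified, dtype=bool)
        self.platform = list(self.platform)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        n, m = self.intensities.shape
        if n != len(self.sample_ids):
            raise ValueError(f"row count {n} != number of sample ids {len(self.sample_ids)}")
        if m != len(self.metabolite_ids):
            raise ValueError(f"column count {m} != number of metabolite ids {len(self.metabolite_ids)}")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.metabolite_ids)) != m:
            raise ValueError("duplicate metabolite ids")
        if self.identified.shape != (m,):
            raise ValueError("identified flag length mismatch")
        if len(self.platform) != m:
            raise ValueError("platform tag length mismatch")
        if m and np.any(np.all(np.isnan(self.intensities), axis=0)):
            bad = [self.metabolite_ids[j] for j in np.flatnonzero(np.all(np.isnan(self.intensities), axis=0))]
            raise ValueError(f"metabolites with all values missing: {bad}")
        with np.errstate(invalid="ignore"):
            if np.any(self.intensities < 0):
                raise ValueError("negative intensities")

    # -- basic accessors ----------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, index=self.sample_ids, columns=self.metabolite_ids)

    # -- subsetting ---------------------------------------------------
    def subset_metabolites(self, metabolite_ids: Sequence[str]) -> "FeatureTable":
        idx = [self.metabolite_ids.index(m) for m in metabolite_ids]
        return FeatureTable(
            sample_ids=list(self.sample_ids),
            metabolite_ids=[self.metabolite_ids[j] for j in idx],
            intensities=self.intensities[:, idx].copy(),
            identified=self.identified[idx].copy(),
            platform=[self.platform[j] for j in idx],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return FeatureTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            metabolite_ids=list(self.metabolite_ids),
            intensities=self.intensities[idx, :].copy(),
            identified=self.identified.copy(),
            platform=list(self.platform),
        )


@dataclass
class StudyPair:
    """Two studies aligned on their shared identified metabolites.

    ``table_a`` and ``table_b`` are restricted and re-ordered to the
    same column order, ``shared_identified``.
    """

    table_a: FeatureTable
    table_b: FeatureTable
    shared_identified: list
    meta_a: Optional[list] = None
    meta_b: Optional[list] = None
    full_a: Optional[FeatureTable] = None
    full_b: Optional[FeatureTable] = None

    def __post_init__(self):
        if self.table_a.metabolite_ids != self.shared_identified:
            raise ValueError("table_a columns not aligned to shared set")
        if [_match_key(m) for m in self.table_b.metabolite_ids] != [
            _match_key(m) for m in self.shared_identified
        ]:
            raise ValueError("table_b columns not aligned to shared set")


def check_meta(table: FeatureTable, meta: Sequence[SampleMeta]) -> dict:
    """Validate the table/metadata join; return sample_id -> SampleMeta."""
    by_id = {}
    for m in meta:
        if m.sample_id in by_id:
            raise ValueError(f"duplicate metadata row for sample {m.sample_id!r}")
        by_id[m.sample_id] = m
    for s in table.sample_ids:
        if s not in by_id:
            raise ValueError(f"missing metadata for sample {s!r}")
    return by_id


def groups_for(table: FeatureTable, meta: Sequence[SampleMeta]) -> list:
    """Group labels aligned to the table's row order."""
    by_id = check_meta(table, meta)
    return [by_id[s].group for s in table.sample_ids]


def select_identified(table: FeatureTable) -> FeatureTable:
    """Restrict a table to its positively identified metabolites.

    The sample set is unchanged; raises if no metabolite is identified.
    """
    keep = [m for m, f in zip(table.metabolite_ids, table.identified) if f]
    if not keep:
        raise ValueError("no identified metabolites in table")
    return table.subset_metabolites(keep)


def intersect_studies(a: FeatureTable, b: FeatureTable) -> StudyPair:
    """Align two studies on the metabolites identified in both.

    Matching is by exact name after trimming and case-folding (no
    synonym matching). The shared list is sorted by name; both
    sub-tables are re-ordered to that common column order.
    """
    keys_a = {_match_key(m): m for m, f in zip(a.metabolite_ids, a.identified) if f}
    keys_b = {_match_key(m): m for m, f in zip(b.metabolite_ids, b.identified) if f}
    shared_keys = sorted(set(keys_a) & set(keys_b))
    if not shared_keys:
        raise ValueError("no identified metabolites shared between the two studies")
    shared = [keys_a[k] for k in shared_keys]
    sub_a = a.subset_metabolites([keys_a[k] for k in shared_keys])
    sub_b = b.subset_metabolites([keys_b[k] for k in shared_keys])
    return StudyPair(table_a=sub_a, table_b=sub_b, shared_identified=shared)
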