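"""Metabolite-level reporting: z-score heat maps and univariate tables.

Standard scores are computed against a reference group's mean and SD on
the raw intensity scale (the display is about relative concentration,
independent of any model scaling), truncated for display, and columns
are ordered by each metabolite's correlation to the diagnosis
(p(corr)), from the largest negative to the largest positive.

Univariate reporting uses two-sided pooled-variance (equal-variance)
Student's t-tests per metabolite, deliberately without multiple-testing
correction: the P values illustrate each metabolite's impact, the
diagnosis itself rests on the multivariate model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .datamodel import FeatureTable, Group, SampleMeta, groups_for, select_identified
from .opls import OplsModel


def standard_scores(table: FeatureTable, meta: Sequence[SampleMeta], reference: Group) -> np.ndarray:
    """Z-scores of every sample against the reference group.

    z_ik = (x_ik - mean_ref,k) / sd_ref,k with the reference group's
    per-metabolite mean and sample SD (n-1 denominator). Metabolites
    with zero reference SD get z = 0 with a warning.
    """
    reference = Group.parse(reference)
    labels = groups_for(table, meta)
    ref_rows = np.array([l is reference for l in labels])
    if ref_rows.sum() < 2:
        raise ValueError(f"reference group {reference.value!r} needs >= 2 samples")
    ref = table.intensities[ref_rows]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(ref, axis=0)
        sd = np.nanstd(ref, axis=0, ddof=1)
    zero = ~(sd > 0)
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} metabolite(s) with zero reference SD; z set to 0", stacklevel=2
        )
    z = np.zeros_like(table.intensities)
    np.divide(table.intensities - mean, sd, out=z, where=~zero)
    z[:, zero] = 0.0
    return z


def truncate_scores(z: np.ndarray, limit: float = 2.0) -> np.ndarray:
    """Clamp standard scores to [-limit, +limit] for display."""
    if limit <= 0:
        raise ValueError("truncation limit must be > 0")
    return np.clip(z, -limit, limit)


@dataclass
class HeatmapMatrix:
    """Truncated z-score matrix with display ordering.

    Rows: samples grouped by class (reference group first). Columns:
    metabolites sorted by p(corr), largest negative to largest
    positive.
    """

    z: np.ndarray
    sample_ids: list
    sample_groups: list
    metabolite_ids: list
    pcorr: np.ndarray
    limit: float

    def __post_init__(self):
        if np.any(np.abs(self.z) > self.limit + 1e-12):
            raise ValueError("entries exceed the truncation limit")
        if np.any(np.diff(self.pcorr) < -1e-12):
            raise ValueError("columns not in ascending p(corr) order")


def build_heatmap(
    table: FeatureTable,
    meta: Sequence[SampleMeta],
    model: OplsModel,
    reference: Group,
    limit: float = 2.0,
) -> HeatmapMatrix:
    """Assemble the z-score heat map for one contrast.

    The model must have been fitted on the same metabolite set (its
    stored p(corr) vector provides the column order).
    """
    if model.pcorr_ is None or len(model.pcorr_) != table.n_metabolites:
        raise ValueError("model p(corr) does not match the table's metabolites")
    reference = Group.parse(reference)
    z = truncate_scores(standard_scores(table, meta, reference), limit)
    order = np.argsort(model.pcorr_, kind="stable")
    labels = groups_for(table, meta)
    row_order = [i for i, l in enumerate(labels) if l is reference] + [
        i for i, l in enumerate(labels) if l is not reference
    ]
    return HeatmapMatrix(
        z=z[np.ix_(row_order, order)],
        sample_ids=[table.sample_ids[i] for i in row_order],
        sample_groups=[labels[i].value for i in row_order],
        metabolite_ids=[table.metabolite_ids[j] for j in order],
        pcorr=model.pcorr_[order],
        limit=limit,
    )


@dataclass
class MetaboliteReport:
    """Per-metabolite univariate + multivariate summary."""

    metabolite_id: str
    mean_ra: float
    sd_ra: float
    mean_ref: float
    sd_ref: float
    t_stat: float
    p_value: float
    direction: str                # "increased" / "decreased" (RA relative to reference)
    significant: bool             # p < 0.05, uncorrected
    pcorr: Optional[float] = None

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must be in (0, 1]")
        if self.pcorr is not None and abs(self.pcorr) > 1.0:
            raise ValueError("p(corr) out of [-1, 1]")


def ttest_table(
    table: FeatureTable,
    meta: Sequence[SampleMeta],
    group_a: Group = Group.RA,
    group_b: Group = Group.CONTROL,
    model: Optional[OplsModel] = None,
    identified_only: bool = True,
    alpha: float = 0.05,
):
    """Two-sided equal-variance t-test per metabolite, group_a vs group_b.

    No multiple-testing correction is applied. Direction is "increased"
    when group_a's mean exceeds group_b's. With a fitted model its
    p(corr) values are attached (the model must cover the same
    metabolite set as the reported table). Zero pooled variance gives
    t = 0, p = 1 with a warning. Only identified metabolites are
    reported unless ``identified_only=False``.
    """
    group_a, group_b = Group.parse(group_a), Group.parse(group_b)
    full = table
    if identified_only:
        table = select_identified(table)
    pc = None
    if model is not None and model.pcorr_ is not None:
        if len(model.pcorr_) == full.n_metabolites:
            by_id = dict(zip(full.metabolite_ids, model.pcorr_))
        elif len(model.pcorr_) == table.n_metabolites:
            by_id = dict(zip(table.metabolite_ids, model.pcorr_))
        else:
            raise ValueError("model p(corr) length matches neither table")
        pc = [by_id[m] for m in table.metabolite_ids]

    labels = groups_for(table, meta)
    rows_a = np.array([l is group_a for l in labels])
    rows_b = np.array([l is group_b for l in labels])
    if rows_a.sum() < 2 or rows_b.sum() < 2:
        raise ValueError("both groups need >= 2 samples")

    reports = []
    for j, mid in enumerate(table.metabolite_ids):
        xa = table.intensities[rows_a, j]
        xb = table.intensities[rows_b, j]
        xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
        mean_a, mean_b = float(xa.mean()), float(xb.mean())
        sd_a = float(xa.std(ddof=1)) if len(xa) > 1 else 0.0
        sd_b = float(xb.std(ddof=1)) if len(xb) > 1 else 0.0
        if sd_a == 0.0 and sd_b == 0.0:
            warnings.warn(f"zero pooled variance for {mid!r}; t=0, p=1", stacklevel=2)
            t_stat, p_val = 0.0, 1.0
        else:
            t_stat, p_val = stats.ttest_ind(xa, xb, equal_var=True)
            t_stat, p_val = float(t_stat), float(max(p_val, np.finfo(float).tiny))
        reports.append(
            MetaboliteReport(
                metabolite_id=mid,
                mean_ra=mean_a,
                sd_ra=sd_a,
                mean_ref=mean_b,
                sd_ref=sd_b,
                t_stat=t_stat,
                p_value=p_val,
                direction="increased" if mean_a > mean_b else "decreased",
                significant=bool(p_val < alpha),
                pcorr=None if pc is None else float(pc[j]),
            )
        )
    return reports


def render_table1(reports: Sequence[MetaboliteReport], alpha: float = 0.05) -> dict:
    """Partition significant metabolites into increased/decreased sections.

    Each section is sorted by ascending P value. Returns a structured
    dict; :func:`table1_text` renders it as plain text.
    """
    sig = [r for r in reports if r.p_value < alpha]
    inc = sorted((r for r in sig if r.direction == "increased"), key=lambda r: r.p_value)
    dec = sorted((r for r in sig if r.direction == "decreased"), key=lambda r: r.p_value)
    return {
        "alpha": alpha,
        "increased": [{"metabolite_id": r.metabolite_id, "p_value": r.p_value} for r in inc],
        "decreased": [{"metabolite_id": r.metabolite_id, "p_value": r.p_value} for r in dec],
    }


def table1_text(rendered: dict, title: str = "Differential metabolites") -> str:
    lines = [title, "=" * len(title), ""]
    for section in ("increased", "decreased"):
        lines.append(section.capitalize())
        rows = rendered[section]
        if not rows:
            lines.append("  (none)")
        for r in rows:
            lines.append(f"  {r['metabolite_id']:<24s} {r['p_value']:.6f}")
        lines.append("")
    return "\n".join(lines)
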