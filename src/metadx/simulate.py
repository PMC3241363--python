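"""Synthetic serum-metabolome cohorts with planted group effects.

The generator emulates the statistical structure a two-group metabolite
classifier has to cope with: log-normal intensities, a handful of
metabolites whose concentration is shifted in one clinical group, a
shared latent nuisance factor (sex/age/sampling/batch style variation
loading on many metabolites but uncorrelated with group), and i.i.d.
measurement noise.

Intensity model, per sample i and metabolite k (natural-log scale)::

    log x_ik = mu_k + shift_ik + lambda_k * z_i + eps_ik

* ``mu_k``     metabolite baseline, drawn once per generator call;
* ``shift_ik`` planted group effect (see below);
* ``z_i``      standard-normal per-sample nuisance latent with
               loadings ``lambda_k ~ N(0, nuisance_sd^2)`` — rank-1
               orthogonal structure. By default the latent is centered
               within each clinical group, making it orthogonal to
               every group contrast by construction (nuisance is
               variation uncorrelated with the diagnosis, so the
               generator enforces that, not just its expectation);
               set ``nuisance_group_centered=False`` for an i.i.d.
               latent with chance group correlation;
* ``eps_ik``   N(0, noise_sd^2) noise.

Planted effects: an RA-vs-control effect shifts the RA group by
``+/- magnitude``; an RA-vs-PsoA effect shifts the PsoA group by the
opposite sign (a marker "decreased" in RA relative to PsoA is raised in
PsoA), so each contrast sees its own marker panel and the RA-vs-control
ranking is not diluted by RA-vs-PsoA markers. Intensities are reported
on the natural (exponentiated) scale. Output is reproducible given the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import List, Optional, Sequence

import numpy as np

from .datamodel import FeatureTable, Group, SampleMeta, StudyPair, intersect_studies


class Contrast(str, Enum):
    RA_VS_CONTROL = "RA_vs_control"
    RA_VS_PSOA = "RA_vs_PsoA"


class Direction(str, Enum):
    INCREASED = "increased"
    DECREASED = "decreased"


@dataclass(frozen=True)
class EffectSpec:
    """One planted marker: which metabolite, which contrast, which way."""

    metabolite_id: str
    contrast: Contrast
    direction: Direction
    magnitude: float = 0.8  # log-scale mean shift

    def __post_init__(self):
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")

    @property
    def sign(self) -> float:
        """Sign of the RA-minus-reference difference."""
        return 1.0 if self.direction is Direction.INCREASED else -1.0


_RA_VS_CONTROL_INCREASED = ["Glyceric acid", "D-ribofuranose", "Hypoxanthine"]
_RA_VS_CONTROL_DECREASED = [
    "Histidine", "Threonic acid", "Methionine", "Cholesterol", "Asparagine", "Threonine",
]
_RA_VS_PSOA_INCREASED = [
    "Glutamine", "Heptanoic acid", "Succinate", "Pseudouridine", "Inosine",
    "Guanosine", "Arabitol", "Cystine", "Cysteine", "Phosphoric acid",
]
_RA_VS_PSOA_DECREASED = [
    "Aspartic acid", "Glutamic acid", "Glutamate", "Histidine", "Serine",
    "Arachidonic acid", "Cholesterol", "Threonic acid", "1-Monooleoylglycerol",
]


def default_effects(magnitude: float = 0.8) -> List[EffectSpec]:
    """The default planted-marker panel: 9 RA-vs-control + 19 RA-vs-PsoA.

    Metabolite names and directions follow the differential metabolites
    reported for the two contrasts; magnitudes are a simulation choice
    (no effect sizes are published, only directions).
    """
    effects = []
    for name in _RA_VS_CONTROL_INCREASED:
        effects.append(EffectSpec(name, Contrast.RA_VS_CONTROL, Direction.INCREASED, magnitude))
    for name in _RA_VS_CONTROL_DECREASED:
        effects.append(EffectSpec(name, Contrast.RA_VS_CONTROL, Direction.DECREASED, magnitude))
    for name in _RA_VS_PSOA_INCREASED:
        effects.append(EffectSpec(name, Contrast.RA_VS_PSOA, Direction.INCREASED, magnitude))
    for name in _RA_VS_PSOA_DECREASED:
        effects.append(EffectSpec(name, Contrast.RA_VS_PSOA, Direction.DECREASED, magnitude))
    return effects


@dataclass
class SimConfig:
    """Cohort-simulation parameters.

    Defaults mirror the modelled study: 21 RA / 9 control / 17 PsoA
    samples with full data, 267 putative metabolites of which 83 are
    identified, and a validation study of 14 RA / 20 controls sharing
    52 identified metabolites with the first.
    """

    n_ra: int = 21
    n_control: int = 9
    n_psoa: int = 17
    n_metabolites: int = 267
    n_identified: int = 83
    n_shared_second_study: int = 52
    n_ra_validation: int = 14
    n_control_validation: int = 20
    n_metabolites_validation: int = 240
    n_identified_validation: int = 60
    effects: List[EffectSpec] = field(default_factory=default_effects)
    nuisance_sd: float = 0.5
    nuisance_group_centered: bool = True
    noise_sd: float = 0.3
    baseline_mean: float = 10.0   # log-intensity location of a typical metabolite
    baseline_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (self.n_shared_second_study <= self.n_identified <= self.n_metabolites):
            raise ValueError("need n_shared_second_study <= n_identified <= n_metabolites")
        counts = [self.n_ra, self.n_control, self.n_psoa]
        if any(c != 0 and c < 2 for c in counts) or self.n_ra < 2 or self.n_control < 2:
            raise ValueError("every generated group needs >= 2 samples")
        if self.nuisance_sd < 0 or self.noise_sd < 0:
            raise ValueError("scales must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        planted = {e.metabolite_id for e in self.effects}
        if len(planted) > self.n_identified:
            raise ValueError("more planted metabolites than identified slots")


@dataclass
class _Panel:
    """Metabolite universe of one study: ids, baselines, nuisance loadings."""

    ids: list
    mu: np.ndarray
    lam: np.ndarray
    identified: np.ndarray
    platform: list


def _planted_names(effects: Sequence[EffectSpec]) -> list:
    seen = []
    for e in effects:
        if e.metabolite_id not in seen:
            seen.append(e.metabolite_id)
    return seen


def _make_panel(config: SimConfig, rng: np.random.Generator, prefix: str = "M") -> _Panel:
    planted = _planted_names(config.effects)
    n_fill_ident = config.n_identified - len(planted)
    n_unident = config.n_metabolites - config.n_identified
    ids = (
        planted
        + [f"{prefix}{j:03d}" for j in range(n_fill_ident)]
        + [f"U-{prefix}{j:03d}" for j in range(n_unident)]
    )
    identified = np.zeros(config.n_metabolites, dtype=bool)
    identified[: config.n_identified] = True
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_metabolites)
    lam = rng.normal(0.0, config.nuisance_sd, size=config.n_metabolites)
    platform = [("GC" if rng.random() < 0.5 else "LC") for _ in range(config.n_metabolites)]
    return _Panel(ids=ids, mu=mu, lam=lam, identified=identified, platform=platform)


def _shift_matrix(panel: _Panel, groups: Sequence[Group], effects: Sequence[EffectSpec]) -> np.ndarray:
    col = {m: j for j, m in enumerate(panel.ids)}
    shift = np.zeros((len(groups), len(panel.ids)))
    ra_rows = np.array([g is Group.RA for g in groups])
    psoa_rows = np.array([g is Group.PSOA for g in groups])
    for e in effects:
        j = col.get(e.metabolite_id)
        if j is None:
            continue
        if e.contrast is Contrast.RA_VS_CONTROL:
            shift[ra_rows, j] += e.sign * e.magnitude
        else:
            shift[psoa_rows, j] += -e.sign * e.magnitude
    return shift


def _sample_cohort(
    panel: _Panel,
    groups: Sequence[Group],
    sample_ids: Sequence[str],
    config: SimConfig,
    rng: np.random.Generator,
    study: str,
) -> tuple:
    n, m = len(groups), len(panel.ids)
    z = rng.normal(size=n)
    if config.nuisance_group_centered:
        # nuisance is defined as variation uncorrelated with the diagnosis:
        # remove its between-group component so it is orthogonal to every
        # group contrast by construction, not just in expectation
        garr = np.array([g.value for g in groups])
        for g in np.unique(garr):
            z[garr == g] -= z[garr == g].mean()
    eps = rng.normal(0.0, config.noise_sd, size=(n, m))
    log_x = panel.mu + _shift_matrix(panel, groups, config.effects) + np.outer(z, panel.lam) + eps
    x = np.exp(log_x)
    if config.missing_rate > 0:
        mask = rng.random(size=(n, m)) < config.missing_rate
        # never blank out a whole metabolite
        full_cols = mask.all(axis=0)
        mask[0, full_cols] = False
        x[mask] = np.nan
    table = FeatureTable(
        sample_ids=list(sample_ids),
        metabolite_ids=list(panel.ids),
        intensities=x,
        identified=panel.identified,
        platform=panel.platform,
    )
    meta = [
        SampleMeta(sample_id=s, group=g, study=study, covariates={"z_nuisance": f"{zi:.6f}"})
        for s, g, zi in zip(sample_ids, groups, z)
    ]
    return table, meta


def _cohort_layout(n_ra: int, n_control: int, n_psoa: int, tag: str = "") -> tuple:
    groups = [Group.RA] * n_ra + [Group.CONTROL] * n_control + [Group.PSOA] * n_psoa
    ids = (
        [f"RA{tag}{i + 1:02d}" for i in range(n_ra)]
        + [f"C{tag}{i + 1:02d}" for i in range(n_control)]
        + [f"P{tag}{i + 1:02d}" for i in range(n_psoa)]
    )
    return groups, ids


def generate_cohort(config: SimConfig) -> tuple:
    """Generate one cohort (feature table + metadata) from a config.

    Same seed, same config => bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    panel = _make_panel(config, rng)
    groups, ids = _cohort_layout(config.n_ra, config.n_control, config.n_psoa)
    return _sample_cohort(panel, groups, ids, config, rng, study="study1")


def generate_study_pair(config: SimConfig) -> StudyPair:
    """Generate a discovery + validation study pair.

    Both studies follow the same effect model. Exactly
    ``n_shared_second_study`` identified metabolite names are shared;
    shared metabolites keep their baselines and nuisance loadings
    across studies (semiquantitative scales comparable between
    cohorts), while sample-level noise and nuisance draws are
    independent. Planted markers are always placed in the shared set.
    The validation study has RA and control samples only.
    """
    rng = np.random.default_rng(config.seed)
    panel1 = _make_panel(config, rng)
    groups1, ids1 = _cohort_layout(config.n_ra, config.n_control, config.n_psoa)
    table1, meta1 = _sample_cohort(panel1, groups1, ids1, config, rng, study="study1")

    # shared identified names: planted markers first, then random others
    ident1 = [m for m, f in zip(panel1.ids, panel1.identified) if f]
    planted = [m for m in _planted_names(config.effects) if m in ident1]
    n_shared = config.n_shared_second_study
    pool = [m for m in ident1 if m not in planted]
    extra_needed = max(0, n_shared - len(planted))
    chosen = list(rng.choice(len(pool), size=extra_needed, replace=False)) if extra_needed else []
    shared = (planted + [pool[i] for i in chosen])[:n_shared]

    # validation panel: shared metabolites reuse study-1 parameters
    n_ident2 = max(config.n_identified_validation, n_shared)
    n2 = max(config.n_metabolites_validation, n_ident2)
    idx1 = {m: j for j, m in enumerate(panel1.ids)}
    ids2 = shared + [f"V{j:03d}" for j in range(n_ident2 - n_shared)] + [
        f"U-V{j:03d}" for j in range(n2 - n_ident2)
    ]
    mu2 = rng.normal(config.baseline_mean, config.baseline_sd, size=n2)
    lam2 = rng.normal(0.0, config.nuisance_sd, size=n2)
    for j, m in enumerate(shared):
        mu2[j] = panel1.mu[idx1[m]]
        lam2[j] = panel1.lam[idx1[m]]
    identified2 = np.zeros(n2, dtype=bool)
    identified2[:n_ident2] = True
    platform2 = [("GC" if rng.random() < 0.5 else "LC") for _ in range(n2)]
    panel2 = _Panel(ids=ids2, mu=mu2, lam=lam2, identified=identified2, platform=platform2)

    cfg2 = replace(config)  # same effect model and scales
    groups2, raw_ids2 = _cohort_layout(config.n_ra_validation, config.n_control_validation, 0, tag="v")
    table2, meta2 = _sample_cohort(panel2, groups2, raw_ids2, cfg2, rng, study="validation")

    pair = intersect_studies(table1, table2)
    pair.meta_a, pair.meta_b = meta1, meta2
    pair.full_a, pair.full_b = table1, table2
    return pair
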