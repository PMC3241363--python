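"""Column-wise preprocessing: imputation, log transform, centering, scaling.

A :class:`Scaler` is fitted on training rows only and then applied to
both training and held-out data, so cross-validation never leaks
held-out information into the preprocessing parameters.

Scaling modes
-------------
``uv``
    Unit variance: divide each centered column by its sample SD
    (n-1 denominator). The conventional default for discriminant
    modelling of metabolomics feature tables.
``pareto``
    Divide by the square root of the SD; down-weights but does not
    fully flatten high-variance metabolites.
``center_only``
    Mean centering only.

Missing values are imputed with the half-minimum rule (half the
observed training minimum of that metabolite) before any transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

MODES = ("uv", "pareto", "center_only")


def impute_missing(X: np.ndarray, half_min: Optional[np.ndarray] = None) -> np.ndarray:
    """Replace missing entries by half the observed column minimum.

    With ``half_min`` given (training-derived fill values), those are
    used instead of the matrix's own minima.
    """
    X = np.asarray(X, dtype=float).copy()
    if not np.any(np.isnan(X)):
        return X
    if half_min is None:
        if np.any(np.all(np.isnan(X), axis=0)):
            raise ValueError("column with all values missing cannot be imputed")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            half_min = 0.5 * np.nanmin(X, axis=0)
    rows, cols = np.nonzero(np.isnan(X))
    X[rows, cols] = np.asarray(half_min)[cols]
    return X


@dataclass
class Scaler:
    """Per-metabolite centering/scaling state fitted on one training set."""

    center: np.ndarray
    scale: np.ndarray
    mode: str
    log_applied: bool
    half_min: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown scaling mode {self.mode!r}")
        if np.any(self.scale <= 0):
            raise ValueError("scale must be positive for every metabolite")

    @property
    def n_features(self) -> int:
        return self.center.shape[0]


def fit_scaler(X: np.ndarray, mode: str = "uv", log: bool = False) -> Scaler:
    """Fit centering/scaling parameters on training intensities.

    Zero-SD metabolites get scale 1 with a warning. With ``log=True``
    the natural log is taken first; non-positive values are an error.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 training samples")
    if mode not in MODES:
        raise ValueError(f"unknown scaling mode {mode!r}")
    if np.any(np.all(np.isnan(X), axis=0)):
        raise ValueError("metabolite with all training values missing")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        half_min = 0.5 * np.nanmin(X, axis=0)
    X = impute_missing(X, half_min)
    if log:
        if np.any(X <= 0):
            raise ValueError("log transform requires strictly positive intensities")
        X = np.log(X)

    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = sd <= 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} constant metabolite(s); scale set to 1", stacklevel=2)
        sd = np.where(zero, 1.0, sd)
    if mode == "uv":
        scale = sd
    elif mode == "pareto":
        scale = np.sqrt(sd)
    else:
        scale = np.ones_like(sd)
    scale = np.where(zero, 1.0, scale)
    return Scaler(center=center, scale=scale, mode=mode, log_applied=log, half_min=half_min)


def apply_scaler(scaler: Scaler, X: np.ndarray) -> np.ndarray:
    """Impute, optionally log, then center and scale with fitted parameters."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != scaler.n_features:
        raise ValueError(
            f"column count {X.shape[1]} does not match fitted scaler ({scaler.n_features})"
        )
    X = impute_missing(X, scaler.half_min)
    if scaler.log_applied:
        if np.any(X <= 0):
            raise ValueError("log transform requires strictly positive intensities")
        X = np.log(X)
    return (X - scaler.center) / scaler.scale


def inverse_scaler(scaler: Scaler, Xs: np.ndarray) -> np.ndarray:
    """Undo centering/scaling (and the log transform); for round-trip checks."""
    X = np.asarray(Xs, dtype=float) * scaler.scale + scaler.center
    if scaler.log_applied:
        X = np.exp(X)
    return X
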