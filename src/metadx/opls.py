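"""Single-response OPLS and OPLS-DA: fitting, prediction, p(corr).

Orthogonal projections to latent structures (OPLS) splits the predictor
matrix into one component predictive of the response and ``n_orth``
components orthogonal (uncorrelated) to it — systematic variation such
as sex, age, sampling or batch effects that would otherwise blur a
discriminant model. With a single response every step is closed-form;
no convergence loop is needed.

Fitting, on column-centered X and centered y, repeats ``n_orth`` times:

1. ``w = X'y / y'y``, normalized to unit length
2. ``t = Xw``; ``p = X't / t't``
3. ``w_orth = p - (w'p) w``, normalized
4. ``t_orth = X w_orth``; ``p_orth = X't_orth / t_orth't_orth``
5. deflate ``X <- X - t_orth p_orth'``

and finally recomputes ``w, t, p`` on the filtered matrix with response
loading ``c = t'y / t't``. The discriminant variant (OPLS-DA) encodes a
two-group contrast as y = +1/-1 (disease group positive), and the
decision threshold on the predicted response is the training mean of y.

``p(corr)``, the correlation between a metabolite's filtered values and
the predictive score vector, is the scale-free measure of each
metabolite's discriminatory capability, bounded in [-1, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datamodel import Group
from .preprocess import Scaler, apply_scaler, fit_scaler

_NORM_TOL = 1e-12


@dataclass
class ClassCoding:
    """Binary +1/-1 encoding of a two-group contrast."""

    positive_label: Group
    negative_label: Group
    y: np.ndarray
    y_center: float


def encode_classes(labels: Sequence, positive: Group) -> ClassCoding:
    """Encode group labels as +1 (positive group) / -1 (the other).

    Exactly two distinct groups must be present, one of them
    ``positive``.
    """
    labels = [Group.parse(l) for l in labels]
    distinct = sorted(set(labels), key=lambda g: g.value)
    if len(distinct) != 2:
        raise ValueError(f"need exactly two groups, got {[g.value for g in distinct]}")
    positive = Group.parse(positive)
    if positive not in distinct:
        raise ValueError(f"positive group {positive.value!r} absent from labels")
    negative = next(g for g in distinct if g != positive)
    y = np.array([1.0 if l == positive else -1.0 for l in labels])
    return ClassCoding(positive_label=positive, negative_label=negative, y=y, y_center=float(y.mean()))


@dataclass
class OplsModel:
    """Fitted OPLS(-DA) model: one predictive + n_orth orthogonal components."""

    w: np.ndarray                 # predictive weights, unit norm
    p: np.ndarray                 # predictive loadings
    c: float                      # response loading
    W_orth: np.ndarray            # (n_features, n_orth) orthogonal weights
    P_orth: np.ndarray            # (n_features, n_orth) orthogonal loadings
    t: np.ndarray                 # training predictive scores
    T_orth: np.ndarray            # (n_samples, n_orth) training orthogonal scores
    n_orth: int
    r2x_pred: float
    r2x_orth: float
    r2y: float
    scaler: Optional[Scaler] = None
    coding: Optional[ClassCoding] = None
    threshold: float = 0.0
    pcorr_: Optional[np.ndarray] = None

    @property
    def y_center(self) -> float:
        return self.coding.y_center if self.coding is not None else 0.0

    def fitted_response(self) -> np.ndarray:
        """Training predictions on the original response scale."""
        return self.t * self.c + self.y_center


def _deflate(X: np.ndarray, model: "OplsModel") -> tuple:
    """Remove the fitted orthogonal components from new (scaled) data."""
    X = X.copy()
    T_orth = np.empty((X.shape[0], model.n_orth))
    for j in range(model.n_orth):
        t_orth = X @ model.W_orth[:, j]
        X -= np.outer(t_orth, model.P_orth[:, j])
        T_orth[:, j] = t_orth
    return X, T_orth


def fit_opls(Xs: np.ndarray, y: np.ndarray, n_orth: int) -> OplsModel:
    """Fit a single-response OPLS model on scaled, centered data.

    Parameters
    ----------
    Xs
        Column-centered (scaled) predictor matrix.
    y
        Centered response vector.
    n_orth
        Number of orthogonal components to extract (>= 0).
    """
    X = np.array(Xs, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if y.shape[0] != n:
        raise ValueError("response length does not match number of rows")
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")
    if n <= n_orth + 1:
        raise ValueError(f"need more than n_orth + 1 = {n_orth + 1} samples, got {n}")
    if np.linalg.norm(y) < _NORM_TOL:
        raise ValueError("response is constant (zero after centering)")

    ss_total = float(np.sum(X * X))
    W_orth = np.empty((d, n_orth))
    P_orth = np.empty((d, n_orth))
    T_orth = np.empty((n, n_orth))

    for j in range(n_orth):
        w = X.T @ y / (y @ y)
        nw = np.linalg.norm(w)
        if nw < _NORM_TOL:
            raise ValueError("predictors carry no covariance with the response")
        w /= nw
        t = X @ w
        p = X.T @ t / (t @ t)
        w_orth = p - (w @ p) * w
        n_wo = np.linalg.norm(w_orth)
        if n_wo < _NORM_TOL:
            raise ValueError(
                f"no orthogonal variation left at component {j + 1}; reduce n_orth"
            )
        w_orth /= n_wo
        t_orth = X @ w_orth
        p_orth = X.T @ t_orth / (t_orth @ t_orth)
        X = X - np.outer(t_orth, p_orth)
        W_orth[:, j], P_orth[:, j], T_orth[:, j] = w_orth, p_orth, t_orth

    w = X.T @ y / (y @ y)
    nw = np.linalg.norm(w)
    if nw < _NORM_TOL:
        raise ValueError("predictors carry no covariance with the response")
    w /= nw
    t = X @ w
    p = X.T @ t / (t @ t)
    c = float(t @ y / (t @ t))

    ss_orth = float(sum((T_orth[:, j] @ T_orth[:, j]) * (P_orth[:, j] @ P_orth[:, j]) for j in range(n_orth)))
    ss_pred = float((t @ t) * (p @ p))
    resid = y - t * c
    r2y = 1.0 - float(resid @ resid) / float(y @ y)

    return OplsModel(
        w=w, p=p, c=c,
        W_orth=W_orth, P_orth=P_orth, t=t, T_orth=T_orth, n_orth=n_orth,
        r2x_pred=ss_pred / ss_total if ss_total > 0 else 0.0,
        r2x_orth=ss_orth / ss_total if ss_total > 0 else 0.0,
        r2y=r2y,
    )


def fit_oplsda(
    X_raw: np.ndarray,
    labels: Sequence,
    positive: Group = Group.RA,
    n_orth: int = 1,
    mode: str = "uv",
    log: bool = True,
) -> OplsModel:
    """Fit scaler + class coding + OPLS on raw intensities (OPLS-DA).

    The decision threshold is the training mean of y, so on balanced
    refits it coincides with classifying by the sign of the centered
    predicted response.
    """
    coding = encode_classes(labels, positive)
    scaler = fit_scaler(np.asarray(X_raw, dtype=float), mode=mode, log=log)
    Xs = apply_scaler(scaler, X_raw)
    model = fit_opls(Xs, coding.y - coding.y_center, n_orth)
    model.scaler = scaler
    model.coding = coding
    model.threshold = coding.y_center
    model.pcorr_ = pcorr(model, Xs)
    return model


def predict(model: OplsModel, X_new: np.ndarray) -> tuple:
    """Predict the response for new samples.

    Raw intensities are scaled with the model's stored scaler (if any),
    the fitted orthogonal components are filtered out sequentially, and
    the predictive score maps to the response via the loading ``c``.

    Returns
    -------
    (y_hat, t_new, T_orth_new)
    """
    X = np.atleast_2d(np.asarray(X_new, dtype=float))
    if model.scaler is not None:
        X = apply_scaler(model.scaler, X)
    elif X.shape[1] != model.w.shape[0]:
        raise ValueError("column count does not match fitted model")
    X, T_orth_new = _deflate(X, model)
    t_new = X @ model.w
    y_hat = t_new * model.c + model.y_center
    return y_hat, t_new, T_orth_new


def classify(model: OplsModel, X_new: np.ndarray):
    """Hard class labels for new samples; ties at the threshold go positive."""
    if model.coding is None:
        raise ValueError("model has no class coding")
    y_hat, _, _ = predict(model, X_new)
    pos, neg = model.coding.positive_label, model.coding.negative_label
    return y_hat, [pos if v >= model.threshold else neg for v in y_hat]


def pcorr(model: OplsModel, Xs: np.ndarray) -> np.ndarray:
    """Correlation of each metabolite with the predictive score vector.

    Computed on the orthogonally filtered training matrix; a metabolite
    with zero variance after filtering gets p(corr) = 0 with a warning.
    """
    X, _ = _deflate(np.asarray(Xs, dtype=float), model)
    t = model.t
    tc = t - t.mean()
    Xc = X - X.mean(axis=0)
    num = Xc.T @ tc
    denom = np.sqrt(np.sum(Xc * Xc, axis=0) * float(tc @ tc))
    zero = denom < _NORM_TOL
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} zero-variance metabolite(s) after filtering; p(corr) set to 0",
            stacklevel=2,
        )
    out = np.zeros(X.shape[1])
    np.divide(num, denom, out=out, where=~zero)
    return np.clip(out, -1.0, 1.0)


def select_n_orth(Xs: np.ndarray, y: np.ndarray, max_orth: int, folds: int = 7, seed: int = 0) -> int:
    """Pick the orthogonal-component count maximizing cross-validated Q2.

    Q2 = 1 - PRESS/SS(y) over ``folds``-fold splits; ties break toward
    the smaller count.
    """
    if max_orth < 0:
        raise ValueError("max_orth must be >= 0")
    X = np.asarray(Xs, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    folds = min(folds, n)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds

    best_q2, best_k = -np.inf, 0
    for k in range(max_orth + 1):
        press = 0.0
        ok = True
        for f in range(folds):
            tr, te = fold_of != f, fold_of == f
            try:
                m = fit_opls(X[tr] - X[tr].mean(axis=0), y[tr] - y[tr].mean(), k)
            except ValueError:
                ok = False
                break
            Xte = X[te] - X[tr].mean(axis=0)
            Xte, _ = _deflate(Xte, m)
            y_hat = Xte @ m.w * m.c + y[tr].mean()
            press += float(np.sum((y[te] - y_hat) ** 2))
        if not ok:
            continue
        q2 = 1.0 - press / float(np.sum((y - y.mean()) ** 2))
        if q2 > best_q2 + 1e-12:
            best_q2, best_k = q2, k
    return best_k


# -- serialization ----------------------------------------------------

def model_to_dict(model: OplsModel) -> dict:
    d = {
        "w": model.w.tolist(),
        "p": model.p.tolist(),
        "c": model.c,
        "W_orth": model.W_orth.tolist(),
        "P_orth": model.P_orth.tolist(),
        "n_orth": model.n_orth,
        "r2x_pred": model.r2x_pred,
        "r2x_orth": model.r2x_orth,
        "r2y": model.r2y,
        "threshold": model.threshold,
    }
    if model.scaler is not None:
        d["scaler"] = {
            "center": model.scaler.center.tolist(),
            "scale": model.scaler.scale.tolist(),
            "mode": model.scaler.mode,
            "log_applied": model.scaler.log_applied,
            "half_min": model.scaler.half_min.tolist(),
        }
    if model.coding is not None:
        d["coding"] = {
            "positive_label": model.coding.positive_label.value,
            "negative_label": model.coding.negative_label.value,
            "y_center": model.coding.y_center,
        }
    return d


def save_model(model: OplsModel, path) -> None:
    """Serialize a fitted model to JSON for refit-free prediction."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def load_model(path) -> OplsModel:
    with open(path) as fh:
        d = json.load(fh)
    scaler = None
    if "scaler" in d:
        s = d["scaler"]
        scaler = Scaler(
            center=np.array(s["center"]),
            scale=np.array(s["scale"]),
            mode=s["mode"],
            log_applied=s["log_applied"],
            half_min=np.array(s["half_min"]),
        )
    coding = None
    if "coding" in d:
        c = d["coding"]
        coding = ClassCoding(
            positive_label=Group.parse(c["positive_label"]),
            negative_label=Group.parse(c["negative_label"]),
            y=np.array([]),
            y_center=c["y_center"],
        )
    n_orth = int(d["n_orth"])
    return OplsModel(
        w=np.array(d["w"]),
        p=np.array(d["p"]),
        c=float(d["c"]),
        W_orth=np.array(d["W_orth"]).reshape(len(d["w"]), n_orth),
        P_orth=np.array(d["P_orth"]).reshape(len(d["w"]), n_orth),
        t=np.array([]),
        T_orth=np.empty((0, n_orth)),
        n_orth=n_orth,
        r2x_pred=float(d["r2x_pred"]),
        r2x_orth=float(d["r2x_orth"]),
        r2y=float(d["r2y"]),
        scaler=scaler,
        coding=coding,
        threshold=float(d["threshold"]),
    )
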