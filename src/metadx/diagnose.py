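"""Cross-validated diagnosis, external-study validation, metrics.

The diagnostic protocol: fit an OPLS-DA model discriminating RA from a
reference group (healthy controls or PsoA), test it with sevenfold
cross-validation in which one-seventh of the samples are left out and
predicted by the model fitted on the rest, repeated until every sample
has been left out once. External validation fits one model on the
discovery study (restricted to the metabolites identified in both
studies) and predicts every sample of the second study.

Preprocessing is refit inside each training fold — a strict no-leakage
policy; ``leaky_scaling=True`` reproduces the looser convention of
scaling once on the full matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datamodel import FeatureTable, Group, SampleMeta, groups_for, intersect_studies
from .opls import OplsModel, encode_classes, fit_opls, fit_oplsda, pcorr, predict
from .preprocess import apply_scaler, fit_scaler


@dataclass
class CvResult:
    """Out-of-fold predictions and classification metrics."""

    sample_ids: list
    fold_of_sample: np.ndarray
    y_true: np.ndarray            # +1/-1 coding of the true groups
    y_hat: np.ndarray             # out-of-fold predicted response
    predicted_class: list
    sensitivity: float
    specificity: float
    q2: float
    confusion: tuple              # (TP, FP, TN, FN)

    def __post_init__(self):
        tp, fp, tn, fn = self.confusion
        if tp + fp + tn + fn != len(self.sample_ids):
            raise ValueError("confusion counts do not sum to n_samples")


def assign_folds(labels: Sequence, k: int = 7, seed: int = 0, stratify: bool = True) -> np.ndarray:
    """Deterministic fold assignment, stratified by class by default.

    Within each class, fold sizes differ by at most one. Raises if a
    class is so small that some training fold would miss it entirely.
    """
    labels = [Group.parse(l) for l in labels]
    n = len(labels)
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if k > n:
        raise ValueError(f"k={k} folds but only {n} samples")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    if stratify:
        # deal classes round-robin through a common random fold order so
        # per-class and overall fold sizes both differ by at most one
        fold_order = rng.permutation(k)
        counter = 0
        for g in sorted(set(labels), key=lambda x: x.value):
            idx = np.array([i for i, l in enumerate(labels) if l == g])
            if k > 1 and len(idx) < 2:
                raise ValueError(f"class {g.value!r} has too few samples to stratify")
            rng.shuffle(idx)
            for i in idx:
                fold_of[i] = fold_order[counter % k]
                counter += 1
    else:
        perm = rng.permutation(n)
        fold_of[perm] = np.arange(n) % k
    for f in range(k):
        train_labels = {labels[i] for i in range(n) if fold_of[i] != f}
        if len(train_labels) < len(set(labels)):
            raise ValueError(f"training set for fold {f} would miss a class")
    return fold_of


def confusion_metrics(true_labels: Sequence, predicted: Sequence, positive: Group) -> tuple:
    """Sensitivity, specificity and the (TP, FP, TN, FN) counts."""
    if len(true_labels) != len(predicted):
        raise ValueError("label vectors differ in length")
    positive = Group.parse(positive)
    t = [Group.parse(l) for l in true_labels]
    p = [Group.parse(l) for l in predicted]
    tp = sum(1 for a, b in zip(t, p) if a is positive and b is positive)
    fn = sum(1 for a, b in zip(t, p) if a is positive and b is not positive)
    tn = sum(1 for a, b in zip(t, p) if a is not positive and b is not positive)
    fp = sum(1 for a, b in zip(t, p) if a is not positive and b is positive)
    if tp + fn == 0:
        raise ValueError("no positive samples: sensitivity undefined")
    if tn + fp == 0:
        raise ValueError("no negative samples: specificity undefined")
    return tp / (tp + fn), tn / (tn + fp), (tp, fp, tn, fn)


def crossval_predict(
    table: FeatureTable,
    meta: Sequence[SampleMeta],
    k: int = 7,
    n_orth: int = 1,
    seed: int = 0,
    positive: Group = Group.RA,
    mode: str = "uv",
    log: bool = True,
    stratify: bool = True,
    leaky_scaling: bool = False,
) -> CvResult:
    """k-fold cross-validated OPLS-DA diagnosis of a two-group table.

    Per fold: fit scaler + OPLS-DA on the remaining folds, predict the
    held-out samples, classify against the fold model's threshold.
    Q2 = 1 - sum((y - y_hat_oof)^2) / sum((y - mean(y))^2).
    """
    labels = groups_for(table, meta)
    coding = encode_classes(labels, positive)
    X = table.intensities
    fold_of = assign_folds(labels, k=k, seed=seed, stratify=stratify)

    y_hat = np.empty(table.n_samples)
    predicted = [None] * table.n_samples
    global_scaler = fit_scaler(X, mode=mode, log=log) if leaky_scaling else None

    for f in range(k):
        tr = fold_of != f
        te = fold_of == f
        tr_labels = [l for l, m in zip(labels, tr) if m]
        if leaky_scaling:
            fold_coding = encode_classes(tr_labels, positive)
            Xs_tr = apply_scaler(global_scaler, X[tr])
            Xs_tr = Xs_tr - Xs_tr.mean(axis=0)
            model = fit_opls(Xs_tr, fold_coding.y - fold_coding.y_center, n_orth)
            model.coding = fold_coding
            model.threshold = fold_coding.y_center
            Xs_te = apply_scaler(global_scaler, X[te]) - apply_scaler(global_scaler, X[tr]).mean(axis=0)
            yh, _, _ = predict(model, Xs_te)
        else:
            model = fit_oplsda(X[tr], tr_labels, positive=positive, n_orth=n_orth, mode=mode, log=log)
            yh, _, _ = predict(model, X[te])
        for j, i in enumerate(np.flatnonzero(te)):
            y_hat[i] = yh[j]
            predicted[i] = (
                model.coding.positive_label if yh[j] >= model.threshold else model.coding.negative_label
            )

    sens, spec, confusion = confusion_metrics(labels, predicted, positive)
    y = coding.y
    q2 = 1.0 - float(np.sum((y - y_hat) ** 2)) / float(np.sum((y - y.mean()) ** 2))
    return CvResult(
        sample_ids=list(table.sample_ids),
        fold_of_sample=fold_of,
        y_true=y,
        y_hat=y_hat,
        predicted_class=predicted,
        sensitivity=sens,
        specificity=spec,
        q2=q2,
        confusion=confusion,
    )


@dataclass
class ValidationResult:
    """External-validation report: one model, per-sample test predictions."""

    shared_identified: list
    train_sample_ids: list
    test_sample_ids: list
    y_hat: np.ndarray
    predicted_class: list
    sensitivity: float
    specificity: float
    confusion: tuple
    model: OplsModel


def external_validate(
    train: FeatureTable,
    train_meta: Sequence[SampleMeta],
    test: FeatureTable,
    test_meta: Sequence[SampleMeta],
    balance: Optional[int] = 9,
    seed: int = 0,
    positive: Group = Group.RA,
    n_orth: int = 1,
    mode: str = "uv",
    log: bool = True,
) -> ValidationResult:
    """Fit on one study, predict every sample of a second study.

    Both tables are first restricted to the metabolites identified in
    both. With ``balance`` set, the training set is subsampled to that
    many observations per group (deterministic given ``seed``) before
    fitting, mirroring a balanced discovery design.
    """
    pair = intersect_studies(train, test)
    tr_tab, te_tab = pair.table_a, pair.table_b

    train_labels = groups_for(tr_tab, train_meta)
    keep = list(range(tr_tab.n_samples))
    if balance is not None:
        rng = np.random.default_rng(seed)
        keep = []
        for g in sorted(set(train_labels), key=lambda x: x.value):
            idx = [i for i, l in enumerate(train_labels) if l == g]
            if balance > len(idx):
                raise ValueError(
                    f"balance={balance} exceeds group {g.value!r} size {len(idx)}"
                )
            keep.extend(sorted(rng.choice(idx, size=balance, replace=False)))
        keep.sort()
    tr_tab = tr_tab.subset_samples([tr_tab.sample_ids[i] for i in keep])
    tr_labels = [train_labels[i] for i in keep]

    model = fit_oplsda(tr_tab.intensities, tr_labels, positive=positive, n_orth=n_orth, mode=mode, log=log)
    y_hat, _, _ = predict(model, te_tab.intensities)
    predicted = [
        model.coding.positive_label if v >= model.threshold else model.coding.negative_label
        for v in y_hat
    ]
    test_labels = groups_for(te_tab, test_meta)
    sens, spec, confusion = confusion_metrics(test_labels, predicted, positive)
    return ValidationResult(
        shared_identified=pair.shared_identified,
        train_sample_ids=list(tr_tab.sample_ids),
        test_sample_ids=list(te_tab.sample_ids),
        y_hat=y_hat,
        predicted_class=predicted,
        sensitivity=sens,
        specificity=spec,
        confusion=confusion,
        model=model,
    )
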