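"""Shrinkage-LDA base classifiers and the two-layer meta-classifier.

The binary discriminant is classic LDA with the pooled within-class
covariance replaced by the convex combination ``(1-lambda) S + lambda nu I``,
where ``nu = trace(S)/D`` and the intensity ``lambda`` follows the
Ledoit-Wolf analytic formula computed on the class-mean-centered training
samples. Shrinking toward the scaled identity ``nu I`` keeps the estimator
invariant to the feature units; a strict unscaled-identity target is
available for comparison.

The hierarchical (meta) classifier trains one base sLDA per modality, turns
their continuous decision values into a 2- or 3-dimensional feature vector,
and fits a second sLDA on top. By default the meta-training decision values
are produced out-of-fold by an inner stratified cross-validation so the meta
layer never sees resubstitution outputs; a ``naive`` resubstitution mode is
provided for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold

from hbcikit.features import FeatureMatrix


class EstimationError(ValueError):
    """Not enough data to estimate the model."""


class PredictionError(ValueError):
    """Model/input mismatch at prediction time."""


def ledoit_wolf_lambda(samples: np.ndarray) -> Tuple[float, float]:
    """Analytic shrinkage intensity toward the scaled identity.

    ``samples`` are n x D observations already centered (for LDA: each class
    mean removed). Returns ``(lambda, nu)`` where ``nu = trace(S)/D`` is the
    target scale and ``lambda`` in [0, 1] estimates the intensity minimizing
    the expected Frobenius risk of ``(1-lambda) S + lambda nu I``:
    the summed variance of the covariance entries divided by the summed
    squared distance of ``S`` from the target.

    Variances use the finite-sample unbiased scaling of Schaefer & Strimmer,
    the convention of shrinkage LDA in the neurophysiology literature; it
    equals the original Ledoit-Wolf intensity up to a factor ``n/(n-1)``,
    which matters only for very small n. Degenerate input (zero sample
    covariance) yields ``lambda = 1`` with ``nu = 0``.
    """
    X = np.asarray(samples, dtype=float)
    n, D = X.shape
    if n < 2:
        raise EstimationError("need at least 2 samples for shrinkage estimation")
    Wbar = X.T @ X / n                      # mean of x_k x_k^T
    S = n / (n - 1) * Wbar                  # unbiased covariance
    nu = np.trace(S) / D
    d2 = np.sum((S - nu * np.eye(D)) ** 2)
    if d2 <= 0:
        return 1.0, float(nu)
    # sum_k ||x_k x_k^T - Wbar||^2 = sum_k ||x_k||^4 - n ||Wbar||^2
    sq_norms = np.einsum("ij,ij->i", X, X)
    var_sum = n / (n - 1) ** 3 * (np.sum(sq_norms ** 2) - n * np.sum(Wbar ** 2))
    lam = float(np.clip(var_sum / d2, 0.0, 1.0))
    return lam, float(nu)


@dataclass
class SLDAModel:
    """Binary shrinkage-LDA discriminant ``f(x) = w . x - b``.

    Positive decision values map to ``class_pair[0]``; an exact zero is
    resolved to ``class_pair[1]`` (documented deterministic tie-break).
    """

    w: np.ndarray
    b: float
    lam: float
    nu: float
    class_pair: Tuple[str, str]
    feature_names: Tuple[str, ...]


def fit_slda(features: FeatureMatrix, class_pair: Tuple[str, str],
             shrinkage: Optional[float] = None,
             target: str = "scaled_identity") -> SLDAModel:
    """Fit a binary shrinkage LDA.

    ``shrinkage=None`` uses the analytic Ledoit-Wolf intensity; a float in
    [0, 1] forces that value. ``target='identity'`` shrinks toward the
    unscaled identity matrix instead of ``nu I``.
    """
    masks = [features.labels == c for c in class_pair]
    if not (masks[0].any() and masks[1].any()):
        missing = [c for c, m in zip(class_pair, masks) if not m.any()]
        raise EstimationError(f"training data lacks class(es) {missing}")
    X = features.values
    D = X.shape[1]
    mus = [X[m].mean(axis=0) for m in masks]
    centered = np.vstack([X[m] - mu for m, mu in zip(masks, mus)])
    lam_auto, _ = ledoit_wolf_lambda(centered)
    lam = lam_auto if shrinkage is None else float(np.clip(shrinkage, 0.0, 1.0))
    n = centered.shape[0]
    S = centered.T @ centered / max(1, n - 2)   # pooled within-class (2 classes)
    nu = float(np.trace(S) / D)
    tgt = nu * np.eye(D) if target == "scaled_identity" else np.eye(D)
    S_shrunk = (1.0 - lam) * S + lam * tgt
    if not np.any(S_shrunk):
        # all samples identical: fall back to the mean-difference direction
        S_shrunk = np.eye(D)
    diff = mus[0] - mus[1]
    w = np.linalg.solve(S_shrunk, diff)
    b = float(w @ (mus[0] + mus[1]) / 2.0)
    return SLDAModel(w=w, b=b, lam=lam, nu=nu, class_pair=tuple(class_pair),
                     feature_names=features.feature_names)


def decision_values(model: SLDAModel, values: np.ndarray) -> np.ndarray:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != model.w.size:
        raise PredictionError(
            f"feature dimension {values.shape[1]} != model dimension {model.w.size}")
    return values @ model.w - model.b


def predict_slda(model: SLDAModel, features: FeatureMatrix | np.ndarray
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Continuous decision values and hard labels for each trial."""
    values = features.values if isinstance(features, FeatureMatrix) else features
    f = decision_values(model, values)
    labels = np.where(f > 0, model.class_pair[0], model.class_pair[1])
    return f, labels


# ---------------------------------------------------------------------------
# meta-classification


@dataclass
class MetaModel:
    """Two-layer classifier: per-modality sLDAs feeding a second-layer sLDA."""

    base: Dict[str, SLDAModel]
    combination: Tuple[str, ...]
    meta: SLDAModel
    class_pair: Tuple[str, str]
    inner_folds: int


def _check_aligned(features: Mapping[str, FeatureMatrix],
                   combination: Sequence[str]) -> np.ndarray:
    ref = None
    for mod in combination:
        if mod not in features:
            raise PredictionError(f"missing modality {mod!r}")
        labels = features[mod].labels
        if ref is None:
            ref = labels
        elif not np.array_equal(ref, labels):
            raise PredictionError("modalities are not aligned on the same trials")
    assert ref is not None
    return ref


def fit_meta(train_features: Mapping[str, FeatureMatrix],
             class_pair: Tuple[str, str],
             combination: Sequence[str] = ("EEG", "HbR", "HbO"),
             inner_folds: int = 5, mode: str = "cv", seed: int = 0) -> MetaModel:
    """Fit base sLDAs per modality plus the second-layer sLDA.

    ``mode='cv'`` (default) generates the meta-training decision values
    out-of-fold with an inner stratified cross-validation, then refits the
    base models on all training trials for deployment. ``mode='naive'``
    trains the meta layer on resubstitution outputs.
    """
    combination = tuple(combination)
    labels = _check_aligned(train_features, combination)
    n = labels.size
    min_class = min(int((labels == c).sum()) for c in class_pair)
    folds = inner_folds
    if mode == "cv" and folds > min_class:
        folds = max(2, min_class)
        warnings.warn(
            f"reducing inner folds from {inner_folds} to {folds} "
            "(too few trials per class)", RuntimeWarning)

    meta_inputs = np.zeros((n, len(combination)))
    if mode == "cv":
        # stratify on class x session (when sessions are known) so block
        # effects stay balanced between the inner folds
        sess = np.asarray(train_features[combination[0]].session_ids)
        strata = np.char.add(labels.astype(str), sess.astype(str))
        if np.unique(strata).size >= folds and \
                np.bincount(np.unique(strata, return_inverse=True)[1]).min() >= folds:
            split_on = strata
        else:
            split_on = labels
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for tr, te in skf.split(np.zeros(n), split_on):
            for j, mod in enumerate(combination):
                m = fit_slda(train_features[mod].subset(tr), class_pair)
                meta_inputs[te, j] = decision_values(
                    m, train_features[mod].values[te])
    elif mode == "naive":
        for j, mod in enumerate(combination):
            m = fit_slda(train_features[mod], class_pair)
            meta_inputs[:, j] = decision_values(m, train_features[mod].values)
    else:
        raise ValueError(f"unknown meta mode {mode!r}")

    any_fm = train_features[combination[0]]
    meta_fm = FeatureMatrix(meta_inputs, labels.copy(),
                            any_fm.session_ids.copy(), combination)
    meta = fit_slda(meta_fm, class_pair)
    base = {mod: fit_slda(train_features[mod], class_pair) for mod in combination}
    return MetaModel(base=base, combination=combination, meta=meta,
                     class_pair=tuple(class_pair), inner_folds=folds)


def predict_meta(model: MetaModel, test_features: Mapping[str, FeatureMatrix]
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Final labels and decision values from the deployed two-layer model."""
    _check_aligned(test_features, model.combination)
    cols = [decision_values(model.base[mod], test_features[mod].values)
            for mod in model.combination]
    f, labels = predict_slda(model.meta, np.column_stack(cols))
    return f, labels
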