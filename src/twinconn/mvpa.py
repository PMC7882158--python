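"""Multivariate pattern analysis: linear SVM over whole-brain edge vectors.

Subjects are classified from their full EC / FC / combined edge patterns
with a soft-margin linear SVM (C = 1) under leave-one-out
cross-validation.  Features are z-scored per training fold (the held-out
subject never contributes to the standardization statistics — fold
hygiene), a training-fold-constant feature is centred to zero.  The
significance of the LOOCV accuracy is calibrated by rerunning the entire
LOOCV under label permutations (class sizes preserved) and reporting the
fraction of chance-level accuracies >= the true accuracy; a fraction of
exactly 0 is reported as p < 1/n_perm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from .containers import ClassificationResult

__all__ = [
    "SVMConfig",
    "FeatureAssembly",
    "combine_features",
    "loocv_svm",
    "permutation_accuracy_test",
    "one_vs_rest_classification",
    "top_weight_edges",
    "OverlapReport",
    "univariate_overlap",
]


@dataclass(frozen=True)
class SVMConfig:
    """Linear soft-margin SVM settings (kernel is fixed linear)."""

    c: float = 1.0


@dataclass
class FeatureAssembly:
    """Concatenated per-subject feature blocks with a combined edge index.

    ``block_slices`` records where each named block (e.g. "ec", "fc",
    "extra") lives in the combined vector; ``index`` maps every combined
    position to ``(block_name, edge_name)``.
    """

    x: np.ndarray
    block_slices: dict[str, slice]
    index: list[tuple[str, object]] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.x.shape[1]


def combine_features(
    blocks: Mapping[str, tuple[np.ndarray, Sequence]],
) -> FeatureAssembly:
    """Concatenate named feature blocks in declared order.

    ``blocks`` maps a block name to ``(subjects x features array,
    per-feature edge index)``.  All blocks must cover the same subjects
    in the same order.
    """
    if not blocks:
        raise ValueError("no feature blocks given")
    mats, index, slices = [], [], {}
    n_subjects = None
    offset = 0
    for name, (mat, edge_index) in blocks.items():
        mat = np.asarray(mat, dtype=float)
        if mat.ndim != 2:
            raise ValueError(f"block {name!r} must be subjects x features")
        if n_subjects is None:
            n_subjects = mat.shape[0]
        elif mat.shape[0] != n_subjects:
            raise ValueError(
                f"block {name!r} has {mat.shape[0]} subjects, expected {n_subjects}"
            )
        if len(edge_index) != mat.shape[1]:
            raise ValueError(f"block {name!r}: index length != feature count")
        mats.append(mat)
        slices[name] = slice(offset, offset + mat.shape[1])
        index.extend((name, e) for e in edge_index)
        offset += mat.shape[1]
    return FeatureAssembly(x=np.hstack(mats), block_slices=slices, index=index)


def _standardize_fold(xtr: np.ndarray, xte: np.ndarray):
    mean = xtr.mean(axis=0)
    sd = xtr.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)  # constant feature -> centred to 0
    return (xtr - mean) / sd, (xte - mean) / sd


def loocv_svm(
    features: np.ndarray,
    labels: Sequence[str],
    config: SVMConfig = SVMConfig(),
) -> ClassificationResult:
    """Leave-one-out linear-SVM classification of two classes.

    Each subject is predicted by an SVM trained on all others, with
    features z-scored by training-fold statistics only.  Returns the
    overall accuracy, per-fold predictions and the mean signed weight
    vector over folds (in standardized-feature space).
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if x.ndim != 2 or x.shape[0] != labels.shape[0]:
        raise ValueError("features must be subjects x features, one label each")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"exactly 2 classes required, got {classes.size}")
    if min((labels == c).sum() for c in classes) < 2:
        raise ValueError("each class needs >= 2 subjects")
    n = x.shape[0]
    preds = np.empty(n, dtype=labels.dtype)
    weights = np.zeros(x.shape[1])
    train_mask = np.ones(n, dtype=bool)
    for i in range(n):
        train_mask[i] = False
        xtr, xte = _standardize_fold(x[train_mask], x[i : i + 1])
        clf = SVC(kernel="linear", C=config.c)
        clf.fit(xtr, labels[train_mask])
        preds[i] = clf.predict(xte)[0]
        weights += clf.coef_[0]
        train_mask[i] = True
    accuracy = float((preds == labels).mean())
    return ClassificationResult(
        accuracy=accuracy,
        per_fold_predictions=preds,
        mean_weights=weights / n,
        classes=tuple(str(c) for c in classes),
    )


def permutation_accuracy_test(
    features: np.ndarray,
    labels: Sequence[str],
    n_perm: int = 1000,
    seed=0,
    config: SVMConfig = SVMConfig(),
) -> ClassificationResult:
    """Permutation-calibrated LOOCV accuracy.

    Each of the ``n_perm`` permutations shuffles the label vector (class
    sizes are automatically preserved) and reruns the complete LOOCV; the
    p value is the fraction of chance accuracies >= the true accuracy.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    true = loocv_svm(features, labels, config)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = loocv_svm(features, rng.permutation(labels), config).accuracy
    p = float((null >= true.accuracy).mean())
    return ClassificationResult(
        accuracy=true.accuracy,
        per_fold_predictions=true.per_fold_predictions,
        mean_weights=true.mean_weights,
        classes=true.classes,
        null_accuracies=null,
        p_value=p,
        n_perm=n_perm,
    )


def one_vs_rest_classification(
    features: np.ndarray,
    labels: Sequence[str],
    positive_class: str,
    n_perm: int | None = None,
    seed=0,
    config: SVMConfig = SVMConfig(),
) -> ClassificationResult:
    """Binary LOOCV-SVM of one class against all remaining subjects pooled."""
    labels = np.asarray(labels)
    if positive_class not in labels:
        raise ValueError(f"positive class {positive_class!r} not present")
    binary = np.where(labels == positive_class, positive_class, "rest")
    if n_perm:
        return permutation_accuracy_test(features, binary, n_perm, seed, config)
    return loocv_svm(features, binary, config)


def top_weight_edges(
    mean_weights: np.ndarray,
    fraction: float = 0.01,
    index: Sequence | None = None,
) -> list[tuple[object, float]]:
    """The ceil(fraction * E) edges with the largest |mean weight|.

    Ties are broken by fixed edge order (lower index first).  Returns
    ``(edge_name, signed_weight)`` pairs, largest |weight| first.
    """
    w = np.asarray(mean_weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty weight vector")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = ceil(fraction * w.size)
    order = np.lexsort((np.arange(w.size), -np.abs(w)))[:k]
    names = index if index is not None else list(range(w.size))
    return [(names[i], float(w[i])) for i in order]


@dataclass
class OverlapReport:
    """Intersection between top-weight edges and univariately significant ones."""

    overlap: list
    n_overlap: int
    n_top: int
    n_significant: int
    in_both: dict


def univariate_overlap(
    top_edges: Sequence, significant_edges: Sequence, universe: Sequence | None = None
) -> OverlapReport:
    """Overlap of a top-weight edge list with the significant-edge list.

    ``top_edges`` may be names or ``(name, weight)`` pairs.  If a
    ``universe`` of valid edge names is given, membership of every input
    edge is validated against it.
    """
    # accept the (name, weight) pairs emitted by top_weight_edges
    tops = [
        e[0]
        if isinstance(e, tuple) and len(e) == 2 and isinstance(e[1], (float, np.floating))
        else e
        for e in top_edges
    ]
    sigs = list(significant_edges)
    if universe is not None:
        uni = set(universe)
        stray = [e for e in list(tops) + sigs if e not in uni]
        if stray:
            raise ValueError(f"edges not in the shared index: {stray[:5]}")
    sig_set = set(sigs)
    overlap = [e for e in tops if e in sig_set]
    flags = {e: (e in sig_set) for e in tops}
    return OverlapReport(
        overlap=overlap,
        n_overlap=len(overlap),
        n_top=len(tops),
        n_significant=len(sigs),
        in_both=flags,
    )
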