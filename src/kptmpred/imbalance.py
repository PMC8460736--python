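"""Class-imbalance handling, in two stages.

Stage one operates at the dataset level: the modified/unmodified task is
heavily skewed (roughly 1:16), and the unmodified majority is thinned by
*instance hardness* — the estimated probability that a learner assigns
the wrong label to a sample.  Majority samples with the highest hardness
(noisy or boundary cases) are discarded until the classes balance 1:1.
Hardness is measured on the sequence-coupling features, the encoding
that carries most of the modification signal.

Stage two operates at the classifier level: residual skew inside each
per-PTM binary task is absorbed by different-error-cost (DEC) weights,
which scale the SVM misclassification cost per class from the class
counts: W+ = M/(2·M1), W− = M/(2·M2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

from .dataset import BenchmarkDataset
from .errors import DegenerateLabelsError, ShapeError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassWeights:
    """DEC misclassification-cost multipliers derived from class counts."""

    w_pos: float
    w_neg: float
    m: int
    m1: int
    m2: int

    def as_dict(self) -> dict[int, float]:
        """Per-class weights in scikit-learn ``class_weight`` form."""
        return {1: self.w_pos, 0: self.w_neg}


def dec_weights(n_pos: int, n_neg: int) -> ClassWeights:
    """Different-error-cost weights W+ = M/(2·M1), W− = M/(2·M2).

    M is the total sample count, M1/M2 the positive/negative counts; the
    weights multiply the SVM cost C so that the minority class's errors
    cost proportionally more.  Balanced counts give W+ = W− = 1, and
    W+·M1 + W−·M2 = M for any input.
    """
    if n_pos < 1 or n_neg < 1:
        raise DegenerateLabelsError(
            f"need at least one sample per class, got {n_pos} / {n_neg}")
    m = n_pos + n_neg
    return ClassWeights(w_pos=m / (2.0 * n_pos), w_neg=m / (2.0 * n_neg),
                        m=m, m1=n_pos, m2=n_neg)


def instance_hardness(features: np.ndarray, binary_labels: np.ndarray,
                      n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Per-sample hardness 1 − p(true label), estimated out-of-fold.

    The probability comes from a cost-sensitive RBF-SVM with probability
    calibration, trained on the remaining folds of a stratified split so
    no sample's hardness is scored by a model that saw it.  Values lie in
    [0, 1]; high hardness marks samples the learner tends to misclassify.
    """
    features = np.asarray(features, dtype=np.float64)
    binary_labels = np.asarray(binary_labels)
    if features.shape[0] != binary_labels.shape[0]:
        raise ShapeError(
            f"{features.shape[0]} feature rows but {binary_labels.shape[0]} labels")
    classes = np.unique(binary_labels)
    if classes.size < 2:
        raise DegenerateLabelsError("hardness needs both classes present")
    weights = dec_weights(int(np.sum(binary_labels == 1)),
                          int(np.sum(binary_labels == 0)))
    svm = SVC(C=1.0, kernel="rbf", gamma="auto",
              class_weight=weights.as_dict(), random_state=seed,
              cache_size=500)
    clf = CalibratedClassifierCV(svm, method="sigmoid", cv=3, ensemble=False)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    proba = cross_val_predict(clf, features, binary_labels, cv=cv,
                              method="predict_proba")
    class_col = {c: i for i, c in enumerate(np.sort(classes))}
    p_true = proba[np.arange(len(binary_labels)),
                   [class_col[y] for y in binary_labels]]
    return 1.0 - p_true


def undersample_majority(dataset: BenchmarkDataset, hardness: np.ndarray,
                         ratio: float = 1.0) -> BenchmarkDataset:
    """Drop the hardest unmodified samples until majority = ratio × minority.

    Minority (modified) samples are never removed; surviving samples keep
    their window strings, labels and original relative order.  Ties in
    hardness break by original sample index, so runs are reproducible.
    If the requested ratio is already satisfied the dataset is returned
    unchanged with a warning.
    """
    hardness = np.asarray(hardness, dtype=np.float64)
    if hardness.shape[0] != len(dataset):
        raise ShapeError(
            f"{hardness.shape[0]} hardness values for {len(dataset)} samples")
    is_neg = np.array([not s.labels for s in dataset.samples])
    neg_idx = np.flatnonzero(is_neg)
    n_minority = int(len(dataset) - neg_idx.size)
    n_keep = int(round(ratio * n_minority))
    if neg_idx.size <= n_keep:
        logger.warning(
            "majority (%d) already ≤ ratio × minority (%d); nothing removed",
            neg_idx.size, n_keep)
        return BenchmarkDataset(list(dataset.samples), dataset.zeta)
    # lowest hardness survives; stable sort keys ties by original index
    order = neg_idx[np.argsort(hardness[neg_idx], kind="stable")]
    survivors = np.zeros(len(dataset), dtype=bool)
    survivors[~is_neg] = True
    survivors[order[:n_keep]] = True
    kept = [s for s, keep in zip(dataset.samples, survivors) if keep]
    logger.info("undersampling: kept %d of %d unmodified samples (%d modified)",
                n_keep, neg_idx.size, n_minority)
    return BenchmarkDataset(kept, dataset.zeta)


class InstanceHardnessUndersampler(BaseEstimator):
    """Estimator-style wrapper: balance a dataset by instance hardness.

    ``fit_resample(dataset, features)`` scores hardness on the supplied
    feature matrix (by convention the coupling features of the
    modified-vs-unmodified task) and removes the hardest unmodified
    samples down to ``ratio`` times the modified count.  After resampling,
    ``hardness_``, ``kept_mask_`` and ``sample_indices_`` describe the
    decision for audit.
    """

    def __init__(self, ratio: float = 1.0, n_folds: int = 5,
                 random_state: int = 0):
        self.ratio = ratio
        self.n_folds = n_folds
        self.random_state = random_state

    def fit_resample(self, dataset: BenchmarkDataset,
                     features: np.ndarray) -> BenchmarkDataset:
        y = np.array([1 if s.labels else 0 for s in dataset.samples])
        self.hardness_ = instance_hardness(features, y, self.n_folds,
                                           self.random_state)
        resampled = undersample_majority(dataset, self.hardness_, self.ratio)
        surviving = {id(s) for s in resampled.samples}
        self.kept_mask_ = np.array([id(s) in surviving for s in dataset.samples])
        self.sample_indices_ = np.flatnonzero(self.kept_mask_)
        return resampled

    def audit_table(self, dataset: BenchmarkDataset):
        """(window, hardness, kept) rows for the last resampling, as a frame."""
        import pandas as pd

        return pd.DataFrame({
            "window": [s.window for s in dataset.samples],
            "hardness": self.hardness_,
            "kept": self.kept_mask_,
        })
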