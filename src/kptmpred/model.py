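"""Multi-label K-PTM classifier and its cross-validation protocol.

Five binary RBF-SVM classifiers — one per modification type, each with
different-error-cost class weights — are trained on their task's
ANOVA-selected feature columns and combined into one multi-label
predictor: every label whose decision score crosses the threshold is
assigned, and an empty predicted set means "unmodified".  The SVM
optimizer itself is delegated to scikit-learn's SVC with the libSVM
defaults C = 1 and γ = 1/n_features; this module owns the cost wiring,
thresholding, fold logic and reproducibility.

Validation follows repeated stratified k-fold cross-validation (default
5 repeats of 5 folds, seeds 0..4).  Folds come from iterative
multi-label stratification so every label's prevalence is approximately
preserved per fold.  All data-dependent components — coupling model,
scaler, feature ranking, DEC weights, SVMs — are fitted inside the
training folds only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.svm import SVC

from .alphabet import ALPHABET_SIZE, PTM_TYPES
from .dataset import DEFAULT_ZETA
from .encoders import (DEFAULT_K_VALUES, DEFAULT_PSEUDOCOUNT, EnsembleEncoder,
                       _ENCODER_ORDER)
from .errors import DegenerateLabelsError, ShapeError
from .imbalance import dec_weights
from .metrics import MetricsReport, multilabel_metrics
from .selection import AnovaFSelector
from . import aaf

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SVMConfig:
    """Hyperparameters of each binary SVM (libSVM defaults)."""

    C: float = 1.0
    gamma: float | str = "auto"  # "auto" = 1/n_features
    probability: bool = False

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not isinstance(self.gamma, str) and self.gamma <= 0:
            raise ValueError("gamma must be positive")


def train_binary(features: np.ndarray, binary_labels: np.ndarray,
                 config: SVMConfig = SVMConfig(), seed: int = 0):
    """Fit one cost-sensitive RBF-SVM.

    Per-class costs are C·W+ and C·W− with the DEC weights computed from
    the training-split class counts, so the minority class's errors cost
    more.  With ``config.probability`` the SVM is wrapped in sigmoid
    probability calibration (and then exposes ``predict_proba`` instead
    of ``decision_function``).
    """
    y = np.asarray(binary_labels).astype(int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError(
            f"binary task needs both classes, got {n_pos} pos / {n_neg} neg")
    weights = dec_weights(n_pos, n_neg)
    clf = SVC(C=config.C, kernel="rbf", gamma=config.gamma,
              class_weight=weights.as_dict(), random_state=seed,
              cache_size=500)
    if config.probability:
        from sklearn.calibration import CalibratedClassifierCV

        clf = CalibratedClassifierCV(clf, method="sigmoid", cv=3,
                                     ensemble=False)
    clf.fit(np.asarray(features, dtype=np.float64), y)
    return clf


def label_sets_to_indicator(label_sets, ptm_types=PTM_TYPES) -> np.ndarray:
    """(n, 5) binary indicator matrix, columns in ``ptm_types`` order."""
    out = np.zeros((len(label_sets), len(ptm_types)), dtype=int)
    col = {p: i for i, p in enumerate(ptm_types)}
    for i, ls in enumerate(label_sets):
        for lab in ls:
            out[i, col[lab]] = 1
    return out


def indicator_to_label_sets(Y: np.ndarray,
                            ptm_types=PTM_TYPES) -> list[frozenset[str]]:
    return [frozenset(p for p, v in zip(ptm_types, row) if v)
            for row in np.asarray(Y)]


def predict_multilabel(handles: Mapping[str, object],
                       features: Mapping[str, np.ndarray],
                       threshold: str = "decision",
                       ptm_types=PTM_TYPES) -> list[frozenset[str]]:
    """Combine five binary classifiers into label-set predictions.

    ``features[ptm]`` holds the column-subset matrix each classifier was
    trained on.  Each label is assigned independently when its decision
    score exceeds 0 (or its calibrated probability exceeds 0.5 with
    ``threshold="probability"``); an empty set means unmodified.
    """
    scores = {}
    n = None
    for ptm in ptm_types:
        clf, X = handles[ptm], np.asarray(features[ptm])
        if X.shape[1] != clf.n_features_in_:
            raise ShapeError(
                f"{ptm}: {X.shape[1]} columns but classifier expects "
                f"{clf.n_features_in_}")
        if n is None:
            n = X.shape[0]
        elif X.shape[0] != n:
            raise ShapeError("per-task feature matrices disagree on sample count")
        if threshold == "probability" or not hasattr(clf, "decision_function"):
            scores[ptm] = clf.predict_proba(X)[:, list(clf.classes_).index(1)] - 0.5
        else:
            scores[ptm] = clf.decision_function(X)
    return [frozenset(p for p in ptm_types if scores[p][i] > 0)
            for i in range(n)]


class MultiLabelKPTMClassifier(BaseEstimator):
    """Window-in, label-set-out multi-label lysine-PTM classifier.

    ``fit`` takes peptide windows plus a label matrix (n × 5 indicator
    array, or a list of label sets) and learns, strictly from that data:
    the sequence-coupling tables (modified vs unmodified), the
    standardization, one ANOVA top-``n_features`` column subset per PTM
    task (unless ``support`` pins precomputed subsets), the DEC class
    weights, and the five SVMs.  ``predict`` returns an indicator matrix;
    ``predict_label_sets`` returns label sets.

    Parameters
    ----------
    zeta : half-window size (windows are 2ζ+1 long).
    encoders : subset of {"aaf", "be", "cksaap", "coupling"}.
    k_values : CKSAAP spacings.
    pseudocount : additive smoothing for the coupling tables.
    n_features : top-m columns per task by ANOVA F; None keeps all.
    support : optional {ptm: column indices} overriding the internal
        ranking (used for replication with a globally computed ranking).
    C, gamma, probability : SVM settings (libSVM defaults).
    threshold : "decision" (score > 0) or "probability" (p > 0.5;
        requires ``probability=True``).
    random_state : seed for the delegated SVMs.
    """

    def __init__(self, zeta: int = DEFAULT_ZETA,
                 encoders: Sequence[str] = _ENCODER_ORDER,
                 k_values: Sequence[int] = DEFAULT_K_VALUES,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT,
                 n_features: int | None = 100,
                 support: Mapping[str, np.ndarray] | None = None,
                 C: float = 1.0, gamma: float | str = "auto",
                 probability: bool = False, threshold: str = "decision",
                 random_state: int = 0):
        self.zeta = zeta
        self.encoders = encoders
        self.k_values = k_values
        self.pseudocount = pseudocount
        self.n_features = n_features
        self.support = support
        self.C = C
        self.gamma = gamma
        self.probability = probability
        self.threshold = threshold
        self.random_state = random_state

    def n_encoded_features(self) -> int:
        """Ensemble dimension implied by the configuration."""
        width = 2 * self.zeta + 1
        dim = 0
        if "aaf" in self.encoders:
            dim += aaf.N_FACTORS * width
        if "be" in self.encoders:
            dim += ALPHABET_SIZE * width
        if "cksaap" in self.encoders:
            dim += ALPHABET_SIZE ** 2 * len(list(self.k_values))
        if "coupling" in self.encoders:
            dim += 2 * self.zeta
        return dim

    def _as_indicator(self, Y) -> np.ndarray:
        if isinstance(Y, np.ndarray) and Y.ndim == 2:
            return Y.astype(int)
        return label_sets_to_indicator(list(Y))

    def fit(self, X, Y):
        """Fit on windows ``X`` and label matrix / label sets ``Y``."""
        windows = list(X)
        Y = self._as_indicator(Y)
        if len(windows) != Y.shape[0]:
            raise ShapeError(f"{len(windows)} windows but {Y.shape[0]} labels")
        y_any = Y.any(axis=1).astype(int)
        fit_kwargs = {"y": y_any} if "coupling" in self.encoders else {}
        self.featurizer_ = EnsembleEncoder(
            zeta=self.zeta, encoders=self.encoders, k_values=self.k_values,
            pseudocount=self.pseudocount).fit(windows, **fit_kwargs)
        Xenc = self.featurizer_.transform(windows)
        config = SVMConfig(C=self.C, gamma=self.gamma,
                           probability=self.probability)
        self.supports_: dict[str, np.ndarray] = {}
        self.classifiers_: dict[str, SVC] = {}
        self.selector_scores_: dict[str, np.ndarray] = {}
        for i, ptm in enumerate(PTM_TYPES):
            y = Y[:, i]
            n_pos = int(y.sum())
            if n_pos < 2 or y.size - n_pos < 2:
                # task untrainable on this data: head always predicts
                # "no such modification"
                logger.warning("%s: only %d positive sample(s); classifier "
                               "disabled for this task", ptm, n_pos)
                self.supports_[ptm] = np.arange(0)
                self.classifiers_[ptm] = None
                continue
            if self.support is not None:
                sup = np.asarray(self.support[ptm])
            elif self.n_features is not None:
                sel = AnovaFSelector(m=self.n_features).fit(Xenc, y)
                sup = sel.support_
                self.selector_scores_[ptm] = sel.scores_
            else:
                sup = np.arange(Xenc.shape[1])
            self.supports_[ptm] = sup
            self.classifiers_[ptm] = train_binary(
                Xenc[:, sup], y, config, seed=self.random_state)
        self.n_features_in_ = 2 * self.zeta + 1  # window length
        return self

    def _task_features(self, windows) -> dict[str, np.ndarray]:
        Xenc = self.featurizer_.transform(list(windows))
        return {ptm: Xenc[:, sup] for ptm, sup in self.supports_.items()}

    def decision_function(self, X) -> np.ndarray:
        """(n, 5) per-label decision scores, columns in PTM order.

        A head disabled at fit time (too few positives) scores a constant
        −1, i.e. it never asserts its modification.
        """
        feats = self._task_features(X)
        n = next(iter(feats.values())).shape[0]
        cols = []
        for ptm in PTM_TYPES:
            clf = self.classifiers_[ptm]
            if clf is None:
                cols.append(np.full(n, -1.0))
            elif (self.threshold == "probability"
                  or not hasattr(clf, "decision_function")):
                pos_col = list(clf.classes_).index(1)
                cols.append(clf.predict_proba(feats[ptm])[:, pos_col] - 0.5)
            else:
                cols.append(clf.decision_function(feats[ptm]))
        return np.column_stack(cols)

    def predict_label_sets(self, X) -> list[frozenset[str]]:
        scores = self.decision_function(X)
        return [frozenset(p for j, p in enumerate(PTM_TYPES)
                          if scores[i, j] > 0)
                for i in range(scores.shape[0])]

    def predict(self, X) -> np.ndarray:
        """(n, 5) indicator matrix; all-zero rows mean unmodified."""
        return label_sets_to_indicator(self.predict_label_sets(X))

    def score(self, X, Y) -> float:
        """Multi-label (Jaccard) accuracy against truth label sets."""
        truth = indicator_to_label_sets(self._as_indicator(Y))
        return multilabel_metrics(truth, self.predict_label_sets(X)).accuracy


# ---------------------------------------------------------------------------
# Cross-validation protocol

@dataclass(frozen=True)
class CVProtocol:
    """Repeated stratified k-fold settings (defaults: 5 × 5-fold)."""

    n_folds: int = 5
    n_repeats: int = 5
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)

    def __post_init__(self):
        if len(self.seeds) != self.n_repeats:
            raise ValueError("need one seed per repeat")


def iterative_stratification(Y: np.ndarray, n_folds: int,
                             seed: int) -> np.ndarray:
    """Multi-label stratified fold assignment (iterative stratification).

    Greedily places samples label by label, rarest label first, into the
    fold with the largest remaining demand for that label, so each fold
    approximately preserves every label's prevalence.  ``Y`` is an
    indicator matrix; an extra all-negative column is added internally so
    unmodified samples stratify too.  Returns a fold index per sample.
    """
    rng = np.random.default_rng(seed)
    Y = np.asarray(Y, dtype=int)
    none_col = (~Y.any(axis=1)).astype(int)[:, None]
    Yx = np.hstack([Y, none_col])
    n, L = Yx.shape
    desired = np.repeat(Yx.sum(axis=0, keepdims=True) / n_folds, n_folds,
                        axis=0)  # (folds, labels)
    capacity = np.full(n_folds, n / n_folds)
    fold_of = np.full(n, -1)
    remaining = np.ones(n, dtype=bool)
    while remaining.any():
        counts = Yx[remaining].sum(axis=0)
        counts = np.where(counts == 0, np.iinfo(np.int64).max, counts)
        lab = int(np.argmin(counts))
        idx = np.flatnonzero(remaining & (Yx[:, lab] == 1))
        if idx.size == 0:  # leftover samples with no labels at all
            idx = np.flatnonzero(remaining)
        rng.shuffle(idx)
        for i in idx:
            key = desired[:, lab] + 1e-9 * capacity + 1e-12 * rng.random(n_folds)
            f = int(np.argmax(key))
            fold_of[i] = f
            desired[f] -= Yx[i]
            capacity[f] -= 1
            remaining[i] = False
    return fold_of


def _folds_are_trainable(Y: np.ndarray, fold_of: np.ndarray,
                         n_folds: int) -> bool:
    """Every training split keeps ≥2 samples of each class for every PTM
    task that is trainable at all (≥4 positives overall); rarer tasks are
    left to the per-fold head-disabling fallback."""
    totals = Y.sum(axis=0)
    for f in range(n_folds):
        Ytr = Y[fold_of != f]
        for i in range(Y.shape[1]):
            if totals[i] < 4:
                continue
            pos = int(Ytr[:, i].sum())
            if pos < 2 or Ytr.shape[0] - pos < 2:
                return False
    return True


def cross_validate(windows, Y, *, zeta: int = DEFAULT_ZETA,
                   n_folds: int = 5, n_repeats: int = 5,
                   seeds: Sequence[int] | None = None,
                   n_features: int | None = 100,
                   selection_mode: str = "leakage-safe",
                   convention: str = "null",
                   encoders: Sequence[str] = _ENCODER_ORDER,
                   k_values: Sequence[int] = DEFAULT_K_VALUES,
                   pseudocount: float = DEFAULT_PSEUDOCOUNT,
                   C: float = 1.0, gamma: float | str = "auto",
                   return_models: bool = False) -> MetricsReport:
    """Repeated stratified k-fold CV of the full pipeline.

    Per repeat: draw an iteratively stratified ``n_folds`` split (folds
    missing a trainable class for any PTM are re-drawn with a shifted
    seed, logged); per fold fit the entire pipeline on the training
    split and predict the held-out windows; pool the held-out
    predictions and score the five multi-label metrics.  Reports the
    mean ± std over repeats.

    ``selection_mode="global"`` computes the ANOVA ranking once
    on the full dataset and reuses it in every fold (the replication
    protocol); the default re-ranks inside each training fold.
    """
    windows = list(windows)
    Y = (Y.astype(int) if isinstance(Y, np.ndarray) and Y.ndim == 2
         else label_sets_to_indicator(list(Y)))
    if seeds is None:
        seeds = list(range(n_repeats))
    protocol = CVProtocol(n_folds=n_folds, n_repeats=n_repeats,
                          seeds=tuple(seeds))

    support = None
    if selection_mode == "global" and n_features is not None:
        global_clf = MultiLabelKPTMClassifier(
            zeta=zeta, encoders=encoders, k_values=k_values,
            pseudocount=pseudocount, n_features=n_features, C=C, gamma=gamma)
        global_clf.fit(windows, Y)
        support = global_clf.supports_
    elif selection_mode not in ("leakage-safe", "global"):
        raise ValueError(f"unknown selection_mode {selection_mode!r}")

    reports, models = [], []
    for seed in protocol.seeds:
        fold_of = None
        for attempt in range(20):
            cand = iterative_stratification(Y, protocol.n_folds,
                                            seed + 1000 * attempt)
            if _folds_are_trainable(Y, cand, protocol.n_folds):
                fold_of = cand
                break
            logger.info("repeat seed %d: fold draw %d left a PTM class "
                        "untrainable; re-drawing", seed, attempt)
        if fold_of is None:
            raise DegenerateLabelsError(
                "could not draw folds with every PTM class trainable; "
                "a label is too rare for this fold count")
        truth, pred = [], []
        for f in range(protocol.n_folds):
            train = np.flatnonzero(fold_of != f)
            val = np.flatnonzero(fold_of == f)
            clf = MultiLabelKPTMClassifier(
                zeta=zeta, encoders=encoders, k_values=k_values,
                pseudocount=pseudocount, n_features=n_features,
                support=support, C=C, gamma=gamma, random_state=seed)
            clf.fit([windows[i] for i in train], Y[train])
            truth.extend(indicator_to_label_sets(Y[val]))
            pred.extend(clf.predict_label_sets([windows[i] for i in val]))
            if return_models:
                models.append(clf)
        reports.append(multilabel_metrics(truth, pred, convention=convention))
    report = MetricsReport.aggregate(reports, seeds=list(protocol.seeds))
    if return_models:
        report.models = models  # type: ignore[attr-defined]
    return report
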