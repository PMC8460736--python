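"""Feature ranking by one-way ANOVA F and incremental feature selection.

Each feature column is scored by the one-way ANOVA F statistic between
the positive and negative group of a binary PTM task,

    F = (n − k) Σ_i n_i (Ȳ_i − Ȳ)²  /  [(k − 1) Σ_i (n_i − 1) s_i²]

with k = 2 groups; larger F means better group separation.  Features are
ranked per PTM task by descending F.  Incremental feature selection (IFS)
then walks a grid of top-m subsets (m = 50, 100, ..., full dimension),
trains the five per-PTM classifiers on each task's top-m columns, and
picks the m with the best cross-validated multi-label accuracy.

Edge cases: a column with zero within-group variance in both groups gets
F = 0 when the group means agree (no signal) and F = +inf when they
differ (perfect separation); rankings place +inf columns first and the
exported score replaces +inf by the largest finite F observed (times
two) so reports stay finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alphabet import PTM_TYPES
from .errors import ShapeError

logger = logging.getLogger(__name__)

DEFAULT_GRID_STEP = 50


def f_scores(X: np.ndarray, binary_labels: np.ndarray) -> np.ndarray:
    """Vectorized two-group ANOVA F for every column of X.

    Returns one F value per column; +inf marks perfectly separating
    constant-within-group columns (see module docstring).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(binary_labels)
    if X.shape[0] != y.shape[0]:
        raise ShapeError(f"{X.shape[0]} rows but {y.shape[0]} labels")
    groups = [X[y == c] for c in (0, 1)]
    n_i = np.array([g.shape[0] for g in groups], dtype=np.float64)
    if np.any(n_i < 2):
        raise ValueError("each group needs at least 2 samples")
    n = float(X.shape[0])
    k = 2.0
    grand = X.mean(axis=0)
    means = np.stack([g.mean(axis=0) for g in groups])
    between = np.einsum("i,ij->j", n_i, (means - grand) ** 2)
    within = np.zeros(X.shape[1])
    for g, m in zip(groups, means):
        within += ((g - m) ** 2).sum(axis=0)
    num = (n - k) * between
    den = (k - 1.0) * within
    with np.errstate(divide="ignore", invalid="ignore"):
        F = num / den
    F[(den == 0) & (num == 0)] = 0.0
    F[(den == 0) & (num > 0)] = np.inf
    # numerical floor: tiny negative impossible, but guard rounding
    return np.maximum(F, 0.0)


def anova_f(feature_column, binary_labels) -> float:
    """One-way ANOVA F for a single feature column (two groups)."""
    col = np.asarray(feature_column, dtype=np.float64).reshape(-1, 1)
    return float(f_scores(col, binary_labels)[0])


@dataclass
class RankedFeatures:
    """Per-PTM descending-F orderings of the feature columns."""

    column_names: list[str]
    #: ptm type -> indices of all columns, best first
    orders: dict[str, np.ndarray]
    #: ptm type -> finite F score per column (original column order)
    scores: dict[str, np.ndarray]

    def ranking(self, ptm_type: str) -> list[tuple[str, float]]:
        """(column_name, F) pairs, best first, for one PTM task."""
        order = self.orders[ptm_type]
        sc = self.scores[ptm_type]
        return [(self.column_names[i], float(sc[i])) for i in order]

    def top(self, ptm_type: str, m: int) -> np.ndarray:
        return self.orders[ptm_type][:m]


def _rank_order(F: np.ndarray) -> np.ndarray:
    """Indices sorted by descending F; ties broken by ascending index."""
    return np.lexsort((np.arange(F.size), -F))


def _finite_scores(F: np.ndarray) -> np.ndarray:
    if not np.isinf(F).any():
        return F
    finite = F[np.isfinite(F)]
    cap = 2.0 * finite.max() if finite.size and finite.max() > 0 else 1.0
    out = F.copy()
    out[np.isinf(out)] = cap
    return out


def rank_features(X: np.ndarray, column_names,
                  labels_per_ptm: dict[str, np.ndarray]) -> RankedFeatures:
    """Rank every column by ANOVA F, independently per PTM task.

    ``labels_per_ptm`` maps each PTM name to its binary label vector over
    the same samples.  Constant columns score F = 0 and rank last.
    """
    column_names = list(column_names)
    if X.shape[1] != len(column_names):
        raise ShapeError(
            f"{X.shape[1]} columns but {len(column_names)} names")
    orders, scores = {}, {}
    for ptm, y in labels_per_ptm.items():
        F = f_scores(X, y)
        orders[ptm] = _rank_order(F)
        scores[ptm] = _finite_scores(F)
    return RankedFeatures(column_names, orders, scores)


class AnovaFSelector:
    """Keep the top-m columns of a binary task by ANOVA F.

    scikit-learn transformer; ties in F break by ascending column index
    so the selection is deterministic.
    """

    def __init__(self, m: int = 100):
        self.m = m

    def get_params(self, deep=True):
        return {"m": self.m}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        F = f_scores(np.asarray(X), np.asarray(y))
        self.scores_ = _finite_scores(F)
        self.support_ = _rank_order(F)[: self.m]
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


@dataclass
class IFSResult:
    """The IFS curve and its operating point."""

    #: (m, multilabel_accuracy, absolute_false) per grid point
    grid: list[tuple[int, float, float]]
    best_m: int

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.grid, columns=["m", "accuracy", "absolute_false"]
                     ).to_csv(path, index=False)


def ifs_grid(n_features: int, step: int = DEFAULT_GRID_STEP) -> list[int]:
    """m = step, 2·step, ... clamped to end exactly at n_features."""
    grid = list(range(step, n_features + 1, step))
    if not grid or grid[-1] != n_features:
        grid.append(n_features)
    return grid


def incremental_selection(windows, Y, *, zeta, grid_step=DEFAULT_GRID_STEP,
                          n_folds=5, seed=0, encoders=None, k_values=None,
                          pseudocount=None, selection_mode="global",
                          convention="null") -> IFSResult:
    """Sweep top-m feature subsets and pick the best multi-label accuracy.

    For each m on the grid, the five per-PTM cost-sensitive SVMs are
    trained on their task's top-m ANOVA-ranked columns and scored by
    ``n_folds``-fold cross-validation; the returned ``best_m`` maximizes
    accuracy, with ties going to the smaller (more parsimonious) m.

    ``selection_mode`` chooses where the ranking is computed:
    ``"global"`` ranks once on the full dataset before CV (the
    replication default), ``"leakage-safe"`` re-ranks inside every
    training fold.
    """
    from . import model  # local import: model depends on this module

    cfg = {}
    if encoders is not None:
        cfg["encoders"] = encoders
    if k_values is not None:
        cfg["k_values"] = k_values
    if pseudocount is not None:
        cfg["pseudocount"] = pseudocount

    probe = model.MultiLabelKPTMClassifier(zeta=zeta, n_features=None, **cfg)
    n_features = probe.n_encoded_features()
    grid_points = []
    for m in ifs_grid(n_features, grid_step):
        report = model.cross_validate(
            windows, Y, zeta=zeta, n_folds=n_folds, n_repeats=1,
            seeds=[seed], n_features=m, selection_mode=selection_mode,
            convention=convention, **cfg)
        grid_points.append((m, report.accuracy, report.absolute_false))
        logger.info("IFS m=%d: accuracy %.4f, absolute-false %.4f",
                    m, report.accuracy, report.absolute_false)
    best_m = max(grid_points, key=lambda t: (t[1], -t[0]))[0]
    return IFSResult(grid_points, best_m)
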