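"""Multi-label evaluation metrics for label-set predictions.

The five set-theoretic metrics of Chou's multi-label formulation, each
the mean of a per-sample term in [0, 1]:

  aiming          |Y ∩ Y'| / |Y'|          (precision of predicted labels)
  coverage        |Y ∩ Y'| / |Y|           (recall of true labels)
  accuracy        |Y ∩ Y'| / |Y ∪ Y'|      (Jaccard)
  absolute-true   1 iff Y' == Y            (exact match)
  absolute-false  (|Y ∪ Y'| − |Y ∩ Y'|)/L  (Hamming loss)

Y is the observed label set and Y' the predicted one for a sample.  An
unmodified site has an empty PTM set, which would leave the aiming and
coverage ratios 0/0; under the default ``null`` convention the empty set
is represented by an explicit "non-k-ptm" label, so Y and Y' are never
empty and the label universe has L = 6 members.  The alternative
``strict`` convention keeps L = 5 and defines 0/0 := 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import NULL_LABEL, PTM_TYPES
from .errors import ShapeError

LABEL_CONVENTIONS = ("null", "strict")

METRIC_NAMES = ("aiming", "coverage", "accuracy", "absolute_true",
                "absolute_false")


@dataclass
class MetricsReport:
    """The five multi-label metrics, optionally with per-repeat values."""

    aiming: float
    coverage: float
    accuracy: float
    absolute_true: float
    absolute_false: float
    n_samples: int
    n_labels: int
    per_repeat: dict[str, list[float]] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)
    seeds: list[int] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def as_percent(self) -> dict[str, float]:
        return {name: 100.0 * getattr(self, name) for name in METRIC_NAMES}

    def to_table(self) -> str:
        """Human-readable one-row table (metrics as %, ± std if present)."""
        header = ["Aiming", "Coverage", "Accuracy", "Absolute-True",
                  "Absolute-False"]
        cells = []
        for name in METRIC_NAMES:
            text = f"{100 * getattr(self, name):.2f}"
            if name in self.std:
                text += f" ±{100 * self.std[name]:.2f}"
            cells.append(text)
        w = [max(len(h), len(c)) for h, c in zip(header, cells)]
        line1 = "  ".join(h.ljust(n) for h, n in zip(header, w))
        line2 = "  ".join(c.ljust(n) for c, n in zip(cells, w))
        return line1 + "\n" + line2

    @classmethod
    def aggregate(cls, reports: list["MetricsReport"],
                  seeds: list[int] | None = None) -> "MetricsReport":
        """Mean ± std over repeated evaluations (e.g. CV repeats)."""
        per_repeat = {name: [getattr(r, name) for r in reports]
                      for name in METRIC_NAMES}
        means = {name: float(np.mean(v)) for name, v in per_repeat.items()}
        stds = {name: float(np.std(v)) for name, v in per_repeat.items()}
        return cls(**means, n_samples=reports[0].n_samples,
                   n_labels=reports[0].n_labels, per_repeat=per_repeat,
                   std=stds, seeds=list(seeds or []))


def _as_sets(label_sets, universe: frozenset[str]) -> list[frozenset[str]]:
    out = []
    for ls in label_sets:
        s = frozenset(ls)
        extra = s - universe
        if extra:
            raise KeyError(f"label(s) {sorted(extra)} outside universe "
                           f"{sorted(universe)}")
        out.append(s)
    return out


def per_label_auc(Y_true, scores, ptm_types=PTM_TYPES) -> dict[str, float]:
    """Auxiliary per-label ROC AUC from decision scores.

    ``Y_true`` is the (n, 5) indicator matrix and ``scores`` the matching
    per-label decision scores; labels absent from the truth get NaN.
    """
    from sklearn.metrics import roc_auc_score

    Y_true = np.asarray(Y_true)
    scores = np.asarray(scores)
    if Y_true.shape != scores.shape:
        raise ShapeError(
            f"truth {Y_true.shape} and scores {scores.shape} disagree")
    out = {}
    for i, ptm in enumerate(ptm_types):
        col = Y_true[:, i]
        out[ptm] = (float(roc_auc_score(col, scores[:, i]))
                    if 0 < col.sum() < col.size else float("nan"))
    return out


def multilabel_metrics(truth, pred, label_universe=PTM_TYPES,
                       convention: str = "null") -> MetricsReport:
    """Score predicted label sets against observed ones.

    Parameters
    ----------
    truth, pred : sequences of label sets (any iterable of str per sample).
    label_universe : the PTM label names (default: the five K-PTM types).
    convention : ``"null"`` (default) represents the empty set by an
        explicit null label and counts it in L; ``"strict"`` keeps the
        empty set, L = |universe|, and defines 0/0 := 1 for aiming and
        coverage on empty sets.
    """
    if convention not in LABEL_CONVENTIONS:
        raise ValueError(f"convention must be one of {LABEL_CONVENTIONS}")
    universe = frozenset(label_universe)
    truth = _as_sets(truth, universe)
    pred = _as_sets(pred, universe)
    if len(truth) != len(pred):
        raise ShapeError(f"{len(truth)} truth sets but {len(pred)} predictions")
    if not truth:
        raise ShapeError("cannot score zero samples")

    if convention == "null":
        null = frozenset([NULL_LABEL])
        truth = [t or null for t in truth]
        pred = [p or null for p in pred]
        n_labels = len(universe) + 1
    else:
        n_labels = len(universe)

    n = len(truth)
    aiming = coverage = accuracy = abs_true = abs_false = 0.0
    for t, p in zip(truth, pred):
        inter = len(t & p)
        union = len(t | p)
        aiming += inter / len(p) if p else 1.0
        coverage += inter / len(t) if t else 1.0
        accuracy += inter / union if union else 1.0
        abs_true += 1.0 if t == p else 0.0
        abs_false += (union - inter) / n_labels
    return MetricsReport(
        aiming=aiming / n, coverage=coverage / n, accuracy=accuracy / n,
        absolute_true=abs_true / n, absolute_false=abs_false / n,
        n_samples=n, n_labels=n_labels)
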