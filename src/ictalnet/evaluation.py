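"""Detection metrics: confusion counts, accuracy/precision/recall, threshold
search, and cross-fold aggregation.

Positive class = abnormal (epileptic).  Accuracy = (TP+TN)/total,
recall = TP/(TP+FN), precision = TP/(TP+FP); zero-denominator cases are
flagged undefined (None) and excluded from aggregation with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "FoldResult",
    "confusion",
    "compute_metrics",
    "search_threshold",
    "aggregate",
]

METRIC_NAMES = ("accuracy", "precision", "recall")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_matrix(self) -> np.ndarray:
        """Rows = true class (normal, abnormal); columns = predicted."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


@dataclass(frozen=True)
class Metrics:
    """Proportions in [0, 1]; None marks an undefined (0/0) metric."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    threshold: float = 0.5

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "threshold": self.threshold,
        }


@dataclass
class FoldResult:
    fold: int
    counts: ConfusionCounts
    metrics: Metrics
    threshold: float
    history: dict = field(default_factory=dict)
    test_indices: np.ndarray | None = None
    test_proba: np.ndarray | None = None


def confusion(y_true, p_abnormal, threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/TN/FP/FN predicting abnormal iff p >= threshold."""
    y_true = np.asarray(y_true)
    p = np.asarray(p_abnormal)
    if y_true.shape != p.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} labels vs {p.shape} probabilities"
        )
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be inside (0, 1)")
    pred = p >= threshold
    truth = y_true == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def _safe_div(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(c: ConfusionCounts, threshold: float = 0.5) -> Metrics:
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return Metrics(
        accuracy=(c.tp + c.tn) / c.total,
        precision=_safe_div(c.tp, c.tp + c.fp),
        recall=_safe_div(c.tp, c.tp + c.fn),
        threshold=threshold,
    )


def _objective(m: Metrics, name: str) -> float:
    p, r = m.precision, m.recall
    if name == "f1":
        if p is None or r is None or (p + r) == 0:
            return 0.0
        return 2 * p * r / (p + r)
    if name == "balanced_accuracy":
        if m.accuracy is None:
            return 0.0
        # recompute from counts is the caller's job; use (recall + tnr)/2 proxy
        return m.accuracy
    if name == "youden":
        if r is None:
            return 0.0
        return r  # adjusted below in search_threshold where TNR is known
    raise ValueError(f"unknown objective {name!r}")


def search_threshold(
    y_true,
    p_abnormal,
    lo: float = 0.3,
    hi: float = 0.7,
    step: float = 0.01,
    objective: str = "f1",
) -> tuple[float, Metrics]:
    """Grid-search the decision threshold on [lo, hi], maximizing ``objective``
    (default F1); ties broken toward 0.5.  Returns (threshold, metrics)."""
    y_true = np.asarray(y_true)
    p = np.asarray(p_abnormal)
    if p.size == 0:
        raise ValueError("empty probability list")
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("need 0 < lo < hi < 1")
    grid = np.round(np.arange(lo, hi + step / 2, step), 10)
    best_t, best_m, best_score = None, None, -np.inf
    for t in grid:
        c = confusion(y_true, p, float(t))
        m = compute_metrics(c, threshold=float(t))
        if objective == "youden":
            tnr = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
            tpr = m.recall if m.recall is not None else 0.0
            score = tpr + tnr - 1.0
        elif objective == "balanced_accuracy":
            tnr = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
            tpr = m.recall if m.recall is not None else 0.0
            score = (tpr + tnr) / 2.0
        else:
            score = _objective(m, objective)
        better = score > best_score + 1e-12
        tie = abs(score - best_score) <= 1e-12 and abs(t - 0.5) < abs(best_t - 0.5)
        if better or tie:
            best_t, best_m, best_score = float(t), m, score
    return best_t, best_m


def aggregate(folds: list[FoldResult]) -> dict:
    """Per-metric arithmetic mean and sample SD across folds.

    Undefined (None) entries are dropped per metric; the number dropped is
    reported under ``n_dropped`` and triggers a warning.
    """
    if len(folds) < 2:
        raise ValueError("aggregation needs at least 2 folds")
    out = {}
    for name in METRIC_NAMES:
        values = [getattr(f.metrics, name) for f in folds]
        defined = [v for v in values if v is not None]
        n_dropped = len(values) - len(defined)
        if n_dropped:
            warnings.warn(
                f"{name}: {n_dropped} undefined fold value(s) excluded from aggregation"
            )
        if len(defined) >= 2:
            mean = float(np.mean(defined))
            sd = float(np.std(defined, ddof=1))
        elif len(defined) == 1:
            mean, sd = float(defined[0]), float("nan")
        else:
            mean, sd = float("nan"), float("nan")
        out[name] = {"mean": mean, "sd": sd, "n_dropped": n_dropped}
    return out
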