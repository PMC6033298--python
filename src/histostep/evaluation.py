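"""Classification evaluation: ROC curves, AUC, accuracy, precision, recall.

Malignant is the positive class throughout.  AUC is the trapezoidal area
under the ROC curve, which (with ties half-weighted) equals the rank
statistic ``P(score+ > score-) + 0.5 * P(score+ = score-)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "ScoredPatch",
    "EvalReport",
    "roc_curve",
    "auc",
    "threshold_metrics",
    "evaluate",
]

POSITIVE = "malignant"
NEGATIVE = "benign"


@dataclass(frozen=True)
class ScoredPatch:
    """A patch's malignant-class probability and its ground truth."""

    score: float
    truth: str

    def __post_init__(self) -> None:
        if self.truth not in (POSITIVE, NEGATIVE):
            raise ValueError(f"truth must be {POSITIVE!r} or {NEGATIVE!r}")
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")


def _scores_labels(scored: list[ScoredPatch]) -> tuple[np.ndarray, np.ndarray]:
    scores = np.array([s.score for s in scored], dtype=float)
    labels = np.array([s.truth == POSITIVE for s in scored], dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return scores, labels


def roc_curve(scored: list[ScoredPatch]) -> np.ndarray:
    """(FPR, TPR) points at every distinct score threshold, plus endpoints.

    Thresholds sweep from +inf downwards; a patch is called malignant when
    its score >= threshold.  The returned array is monotone nondecreasing in
    both coordinates, from (0, 0) to (1, 1).
    """
    scores, labels = _scores_labels(scored)
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    tps = np.cumsum(labels)
    fps = np.cumsum(~labels)
    # Keep only the last index of each tied-score run.
    last_of_run = np.append(scores[1:] != scores[:-1], True)
    tpr = tps[last_of_run] / n_pos
    fpr = fps[last_of_run] / n_neg
    return np.vstack([[0.0, 0.0], np.column_stack([fpr, tpr])])


def auc(scored: list[ScoredPatch]) -> float:
    """Trapezoidal area under the ROC curve."""
    pts = roc_curve(scored)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def threshold_metrics(
    scored: list[ScoredPatch], threshold: float = 0.5
) -> tuple[float, float, float]:
    """(accuracy, precision, recall) at a fixed operating threshold.

    A patch is called malignant when score >= threshold.  Precision is
    defined as 0 when no patch is called malignant.
    """
    scores, labels = _scores_labels(scored)
    pred = scores >= threshold
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    acc = (tp + tn) / len(labels)
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn)
    return acc, precision, recall


@dataclass
class EvalReport:
    auc: float
    acc: float
    precision: float
    recall: float
    threshold: float
    roc: list[list[float]]
    precision_defined: bool = True

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def evaluate(scored: list[ScoredPatch], threshold: float = 0.5) -> EvalReport:
    """Full report: AUC, threshold metrics, and the ROC polyline."""
    pts = roc_curve(scored)
    area = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    acc, precision, recall = threshold_metrics(scored, threshold)
    scores, labels = _scores_labels(scored)
    any_called = bool((scores >= threshold).any())
    return EvalReport(
        auc=area,
        acc=acc,
        precision=precision,
        recall=recall,
        threshold=threshold,
        roc=pts.tolist(),
        precision_defined=any_called,
    )
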