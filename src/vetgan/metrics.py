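"""Binary-classification evaluation: confusion counts, summary metrics, AUC.

The positive class is "unhealthy" (label 1) — the detection target.
Zero-denominator metrics (e.g. precision with no positive predictions)
return 0 with a logged warning rather than raising, so a sweep over many
models never aborts on one degenerate confusion table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("vetgan")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Standard confusion counts with positive class = unhealthy (1)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if not (np.isin(pred, (0, 1)).all() and np.isin(truth, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (truth == 1))),
        fp=int(np.sum((pred == 1) & (truth == 0))),
        tn=int(np.sum((pred == 0) & (truth == 0))),
        fn=int(np.sum((pred == 0) & (truth == 1))),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("%s has zero denominator; reporting 0", name)
        return 0.0
    return num / den


def summary(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, specificity and F1 from counts."""
    if counts.total == 0:
        raise ValueError("cannot summarize empty confusion counts")
    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = _ratio(counts.tp, counts.tp + counts.fn, "recall")
    if precision + recall == 0.0:
        logger.warning("F1 has zero denominator; reporting 0")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": (counts.tp + counts.tn) / counts.total,
        "precision": precision,
        "recall": recall,
        "specificity": _ratio(counts.tn, counts.tn + counts.fp, "specificity"),
        "f1": f1,
    }


def auc_roc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based ROC AUC with average ranks for ties.

    Equals the probability that a random positive outscores a random
    negative, counting ties as one half (the Mann-Whitney statistic), which
    is the area under the trapezoidal ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos = int(np.sum(truth == 1))
    n_neg = int(np.sum(truth == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(scores: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """FPR/TPR pairs at every score threshold, for external plotting."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    order = np.argsort(-scores, kind="stable")
    truth_sorted = truth[order]
    tps = np.cumsum(truth_sorted == 1)
    fps = np.cumsum(truth_sorted == 0)
    n_pos = max(int(tps[-1]), 1)
    n_neg = max(int(fps[-1]), 1)
    df = pd.DataFrame(
        {
            "threshold": np.concatenate(([np.inf], scores[order])),
            "fpr": np.concatenate(([0.0], fps / n_neg)),
            "tpr": np.concatenate(([0.0], tps / n_pos)),
        }
    )
    return df


def write_report(metrics: dict[str, float], path: str | Path) -> None:
    """One metric per row CSV report."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"metric": list(metrics), "value": [metrics[k] for k in metrics]}
    ).to_csv(path, index=False)
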