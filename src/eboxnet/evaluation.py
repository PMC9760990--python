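"""ROC/AUC and precision with a brute-force-verifiable core.

The AUC here is the Mann-Whitney statistic: the probability that a random
positive outscores a random negative, with ties counted as half a win
(midrank handling, equivalent to trapezoidal interpolation of the ROC curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "EvalResult",
    "UndefinedMetricError",
    "roc_auc",
    "roc_points",
    "precision_at_threshold",
    "evaluate",
    "write_eval_tsv",
]


class UndefinedMetricError(ValueError):
    """A metric whose defining ratio has an empty denominator."""


def _check_two_class(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"both classes required: got {n_pos} positives and {n_neg} negatives"
        )
    return n_pos, n_neg


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via rank statistics.

    Equals P(score+ > score-) + 0.5 * P(score+ == score-) over all
    positive-negative pairs.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos, n_neg = _check_two_class(y)
    ranks = rankdata(s)  # midranks for ties
    pos_rank_sum = ranks[y == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_points(scores, labels) -> np.ndarray:
    """ROC curve as an (n, 2) array of (FPR, TPR), from (0,0) to (1,1).

    One point per distinct score threshold, thresholds descending; tied
    scores contribute a single point (a diagonal segment of the curve).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_two_class(y)
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    # indices where the threshold changes
    distinct = np.nonzero(np.diff(s))[0]
    cut = np.r_[distinct, s.size - 1]
    tp = np.cumsum(y)[cut]
    fp = np.cumsum(1 - y)[cut]
    pts = np.column_stack([fp / n_neg, tp / n_pos])
    return np.vstack([[0.0, 0.0], pts])


def precision_at_threshold(scores, labels, threshold: float = 0.5) -> float:
    """TP / (TP + FP) among scores >= threshold.

    Raises UndefinedMetricError when nothing is predicted positive: the
    quantity is undefined, not zero.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = s >= threshold
    n_pred = int(pred.sum())
    if n_pred == 0:
        raise UndefinedMetricError(
            f"no score reaches threshold {threshold}; precision is undefined"
        )
    return float(y[pred].sum() / n_pred)


@dataclass
class EvalResult:
    auc: float
    precision_at_half: float | None
    n_pos: int
    n_neg: int
    roc_points: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"auc {self.auc} outside [0, 1]")


def evaluate(scores, labels) -> EvalResult:
    """Full evaluation of one score vector against binary labels."""
    y = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_two_class(y)
    try:
        prec = precision_at_threshold(scores, labels)
    except UndefinedMetricError:
        prec = None
    return EvalResult(
        auc=roc_auc(scores, labels),
        precision_at_half=prec,
        n_pos=n_pos,
        n_neg=n_neg,
        roc_points=roc_points(scores, labels),
    )


def write_eval_tsv(result: EvalResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"auc\t{result.auc:.6f}\n")
        prec = "NA" if result.precision_at_half is None else f"{result.precision_at_half:.6f}"
        fh.write(f"precision_at_0.5\t{prec}\n")
        fh.write(f"n_pos\t{result.n_pos}\n")
        fh.write(f"n_neg\t{result.n_neg}\n")
        fh.write("# ROC points: fpr\ttpr\n")
        for fpr, tpr in result.roc_points:
            fh.write(f"{fpr:.6f}\t{tpr:.6f}\n")
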