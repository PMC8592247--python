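"""Confusion-count metrics and rank-based AUC.

Per class, a one-vs-rest confusion table (TP/TN/FP/FN) yields
Accuracy, Precision, Recall and F1; AUC is the Mann-Whitney
(rank/midrank) statistic, and the macro average is the unweighted mean
of per-class AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import multilabel_confusion_matrix, roc_auc_score


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def confusion(
    scores: np.ndarray,
    targets: np.ndarray,
    rule: str = "argmax",
    threshold: float = 0.5,
) -> list[ConfusionCounts]:
    """One-vs-rest confusion counts per class.

    ``rule='argmax'`` (single-label tasks) predicts the top-scoring
    class; ``rule='threshold'`` (multi-label) predicts every class
    whose score exceeds ``threshold``.
    """
    scores = np.asarray(scores)
    targets = np.asarray(targets)
    if scores.size == 0:
        raise ValueError("cannot compute confusion counts on empty input")
    if scores.shape != targets.shape:
        raise ValueError(f"scores {scores.shape} vs targets {targets.shape}")
    if rule == "argmax":
        pred = np.zeros_like(scores, dtype=int)
        pred[np.arange(len(scores)), scores.argmax(axis=1)] = 1
    elif rule == "threshold":
        pred = (scores > threshold).astype(int)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    mats = multilabel_confusion_matrix(targets.astype(int), pred)
    return [
        ConfusionCounts(tp=int(m[1, 1]), tn=int(m[0, 0]), fp=int(m[0, 1]), fn=int(m[1, 0]))
        for m in mats
    ]


def auc(scores: np.ndarray, targets: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    targets = np.asarray(targets)
    if len(np.unique(targets)) < 2:
        raise ValueError(
            "AUC is undefined when only one target value is present"
        )
    return float(roc_auc_score(targets, np.asarray(scores)))


def metrics_report(
    scores: np.ndarray,
    targets: np.ndarray,
    class_names: list[str],
    rule: str = "argmax",
) -> pd.DataFrame:
    """Per-class metrics table plus a macro row.

    Per-class AUC is one-vs-rest; classes whose test targets are
    single-valued get NaN AUC and are excluded from the macro average.
    Zero-denominator precision/recall are reported as 0 and flagged in
    the ``degenerate`` column.
    """
    counts = confusion(scores, targets, rule=rule)
    targets = np.asarray(targets)
    scores = np.asarray(scores)
    rows = []
    aucs = []
    for k, (name, c) in enumerate(zip(class_names, counts)):
        try:
            a = auc(scores[:, k], targets[:, k])
            aucs.append(a)
        except ValueError:
            a = np.nan
        rows.append(
            {
                "class": name,
                "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
                "precision": c.precision,
                "recall": c.recall,
                "accuracy": c.accuracy,
                "f1": c.f1,
                "auc": a,
                "degenerate": (c.tp + c.fp == 0) or (c.tp + c.fn == 0),
            }
        )
    rows.append(
        {
            "class": "macro",
            "tp": sum(c.tp for c in counts),
            "tn": sum(c.tn for c in counts),
            "fp": sum(c.fp for c in counts),
            "fn": sum(c.fn for c in counts),
            "precision": float(np.mean([r["precision"] for r in rows])),
            "recall": float(np.mean([r["recall"] for r in rows])),
            "accuracy": float(np.mean([r["accuracy"] for r in rows])),
            "f1": float(np.mean([r["f1"] for r in rows])),
            "auc": float(np.mean(aucs)) if aucs else np.nan,
            "degenerate": False,
        }
    )
    return pd.DataFrame(rows)


def macro_auc(scores: np.ndarray, targets: np.ndarray) -> float:
    """Unweighted mean one-vs-rest AUC over classes with both outcomes."""
    scores, targets = np.asarray(scores), np.asarray(targets)
    vals = []
    for k in range(targets.shape[1]):
        if len(np.unique(targets[:, k])) == 2:
            vals.append(auc(scores[:, k], targets[:, k]))
    if not vals:
        raise ValueError("no class has both outcomes present")
    return float(np.mean(vals))
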