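"""Per-patient volumetric evaluation: threshold at 0.5, 3D confusion
counts per subject, mean DSC/Recall/Precision across subjects, and a
pooled "global" DSC over all test voxels.

Metric conventions for degenerate volumes (possible with synthetic
data; ATLAS subjects always carry a lesion): an empty truth with an
empty prediction scores DSC 1.0, an empty truth with a nonempty
prediction 0.0; recall with no positives in truth is 1.0; precision
with an empty prediction is 0.0 and the row is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "EvaluationReport", "binarize",
           "confusion_counts", "dsc", "recall", "precision",
           "evaluate_cohort"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxelwise true positives, false positives, false negatives
    (true negatives are implicit)."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn)


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Foreground where probability >= threshold (ties count as lesion)."""
    prob = np.asarray(prob)
    return (prob >= threshold).astype(np.uint8)


def _require_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr.astype(bool)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = _require_binary(pred, "pred")
    truth = _require_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape}, truth {truth.shape}")
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & truth)),
        fp=int(np.count_nonzero(pred & ~truth)),
        fn=int(np.count_nonzero(~pred & truth)),
    )


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient, 2TP / (2TP + FP + FN)."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:  # empty truth, empty prediction
        return 1.0
    return 2 * c.tp / denom


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); 1.0 when the truth has no positives."""
    if c.tp + c.fn == 0:
        return 1.0
    return c.tp / (c.tp + c.fn)


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); 0.0 when nothing was predicted (flagged upstream)."""
    if c.tp + c.fp == 0:
        return 0.0
    return c.tp / (c.tp + c.fp)


@dataclass
class EvaluationReport:
    """Per-patient metric rows plus cohort summaries."""

    per_patient: pd.DataFrame   # subject_id, tp, fp, fn, dsc, recall, precision, empty_prediction
    mean_dsc: float
    mean_recall: float
    mean_precision: float
    global_dsc: float
    pooled: ConfusionCounts

    def summary(self) -> dict:
        return {
            "n_subjects": int(len(self.per_patient)),
            "mean_dsc": self.mean_dsc,
            "mean_recall": self.mean_recall,
            "mean_precision": self.mean_precision,
            "global_dsc": self.global_dsc,
            "pooled_tp": self.pooled.tp,
            "pooled_fp": self.pooled.fp,
            "pooled_fn": self.pooled.fn,
        }


def evaluate_cohort(predictions: Mapping[str, np.ndarray],
                    truths: Mapping[str, np.ndarray],
                    threshold: float = 0.5) -> EvaluationReport:
    """Evaluate per-subject probability volumes against truth masks.

    Each subject's whole 3D volume is thresholded and reduced to one
    confusion-count triple; the report carries unweighted means across
    subjects and the pooled-count global DSC.
    """
    if set(predictions) != set(truths):
        raise ValueError(
            f"subject mismatch: predictions {sorted(predictions)} vs truths {sorted(truths)}")
    if not predictions:
        raise ValueError("no subjects to evaluate")
    rows = []
    pooled = ConfusionCounts(0, 0, 0)
    for sid in sorted(predictions):
        prob, truth = predictions[sid], truths[sid]
        if prob.shape != truth.shape:
            raise ValueError(f"subject {sid}: prediction shape {prob.shape} "
                             f"!= truth shape {truth.shape}")
        c = confusion_counts(binarize(prob, threshold), truth)
        pooled = pooled + c
        rows.append({
            "subject_id": sid, "tp": c.tp, "fp": c.fp, "fn": c.fn,
            "dsc": dsc(c), "recall": recall(c), "precision": precision(c),
            "empty_prediction": bool(c.tp + c.fp == 0),
        })
    df = pd.DataFrame(rows)
    return EvaluationReport(
        per_patient=df,
        mean_dsc=float(df["dsc"].mean()),
        mean_recall=float(df["recall"].mean()),
        mean_precision=float(df["precision"].mean()),
        global_dsc=dsc(pooled),
        pooled=pooled,
    )
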