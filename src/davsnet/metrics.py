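"""Field-of-view-restricted segmentation evaluation.

Vessel pixels are the positive class.  Only pixels inside the FOV mask
are ever counted, so anything outside the imaged retinal disc cannot
influence a score.  Derived metrics:

    Se  = TP / (TP + FN)          (vessel recall, sensitivity)
    Sp  = TN / (TN + FP)          (background recall, specificity)
    Acc = (TP + TN) / total       (pixel accuracy)
    FPR = FP / (FP + TN) = 1 - Sp

plus the area under the ROC curve (trapezoidal; equivalently the
Mann-Whitney concordance probability with ties counted 0.5) and the
area under the precision-recall curve (step-wise / average-precision
integration, whose no-skill baseline equals the vessel prevalence).
Zero-denominator metrics are flagged as NaN rather than silently set
to 0; single-class ROC/PR problems raise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "summary",
    "roc_curve_auc",
    "pr_curve_auc",
    "evaluate",
    "evaluate_set",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level confusion counts over the evaluated (in-FOV) region."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def _check_shapes(*arrays) -> None:
    shapes = {np.asarray(a).shape for a in arrays if a is not None}
    if len(shapes) > 1:
        raise ValueError(f"shape mismatch between masks: {sorted(shapes)}")


def _select(values: np.ndarray, fov: Optional[np.ndarray]) -> np.ndarray:
    values = np.asarray(values)
    if fov is None:
        return values.ravel()
    return values[np.asarray(fov) == 1]


def confusion(pred: np.ndarray, truth: np.ndarray, fov: Optional[np.ndarray] = None) -> ConfusionCounts:
    """Tally TP/FP/TN/FN over in-FOV pixels (vessel = positive class)."""
    _check_shapes(pred, truth, fov)
    p = _select(pred, fov) == 1
    t = _select(truth, fov) == 1
    return ConfusionCounts(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def summary(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(Se, Sp, Acc) from confusion counts; NaN where a denominator is zero."""
    se = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else math.nan
    sp = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else math.nan
    acc = (counts.tp + counts.tn) / counts.total if counts.total else math.nan
    return se, sp, acc


def roc_curve_auc(
    scores: np.ndarray, truth: np.ndarray, fov: Optional[np.ndarray] = None
) -> tuple[pd.DataFrame, float]:
    """ROC curve (thresholds swept over all distinct scores) and its
    trapezoidal area, restricted to the FOV."""
    _check_shapes(scores, truth, fov)
    s = _select(scores, fov).astype(np.float64)
    t = _select(truth, fov) == 1
    if t.all() or not t.any():
        raise ValueError("ROC is undefined: ground truth is single-class within the FOV")
    fpr, tpr, thr = roc_curve(t, s)
    curve = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return curve, float(np.trapezoid(tpr, fpr))


def pr_curve_auc(
    scores: np.ndarray, truth: np.ndarray, fov: Optional[np.ndarray] = None
) -> tuple[pd.DataFrame, float]:
    """Precision-recall curve and its step-wise area (average precision).

    Precision at zero predicted positives is defined as 1.  Raises when
    the FOV contains no vessel pixel.
    """
    _check_shapes(scores, truth, fov)
    s = _select(scores, fov).astype(np.float64)
    t = _select(truth, fov) == 1
    if not t.any():
        raise ValueError("PR curve is undefined: no positive pixels within the FOV")
    precision, recall, thr = precision_recall_curve(t, s)
    curve = pd.DataFrame(
        {
            "threshold": np.append(thr, np.nan),
            "precision": precision,
            "recall": recall,
        }
    )
    return curve, float(average_precision_score(t, s))


@dataclass
class MetricsReport:
    """Per-image and pooled evaluation results.

    ``per_image`` has one row per sample (id, counts, Se, Sp, Acc, FPR,
    AUC, AUCPR); ``pooled`` aggregates by summing confusion counts over
    the set and pooling scores for the curve areas.
    """

    per_image: pd.DataFrame
    pooled: dict

    def summary(self) -> str:
        lines = ["Evaluation report (FOV-restricted, vessel = positive)", "-" * 54]
        for _, row in self.per_image.iterrows():
            lines.append(
                f"{row['id']}: Se={row['se']:.4f} Sp={row['sp']:.4f} Acc={row['acc']:.4f} "
                f"AUC={row['auc_roc']:.4f} AUCPR={row['auc_pr']:.4f}"
            )
        p = self.pooled
        lines.append("-" * 54)
        lines.append(
            f"pooled ({p['n_images']} images): Se={p['se']:.4f} Sp={p['sp']:.4f} "
            f"Acc={p['acc']:.4f} AUC={p['auc_roc']:.4f} AUCPR={p['auc_pr']:.4f}"
        )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        pooled_row = {"id": "pooled", **{k: v for k, v in self.pooled.items() if k != "n_images"}}
        pd.concat([self.per_image, pd.DataFrame([pooled_row])], ignore_index=True).to_csv(
            path, index=False
        )

    def to_json(self, path) -> None:
        payload = {
            "per_image": self.per_image.to_dict(orient="records"),
            "pooled": self.pooled,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def evaluate(
    scores: np.ndarray,
    truth: np.ndarray,
    fov: Optional[np.ndarray] = None,
    threshold: float = 0.5,
    pred: Optional[np.ndarray] = None,
) -> dict:
    """All metrics for one image.

    ``scores`` are per-pixel vessel probabilities; the binary prediction
    defaults to ``scores > threshold`` unless ``pred`` is given.
    """
    if pred is None:
        pred = (np.asarray(scores) > threshold).astype(np.uint8)
    counts = confusion(pred, truth, fov)
    se, sp, acc = summary(counts)
    _, auc_roc = roc_curve_auc(scores, truth, fov)
    _, auc_pr = pr_curve_auc(scores, truth, fov)
    return {
        "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn,
        "se": se, "sp": sp, "acc": acc,
        "fpr": 1.0 - sp if not math.isnan(sp) else math.nan,
        "auc_roc": auc_roc, "auc_pr": auc_pr,
    }


def evaluate_set(
    ids: Sequence,
    scores: Sequence[np.ndarray],
    truths: Sequence[np.ndarray],
    fovs: Optional[Sequence[Optional[np.ndarray]]] = None,
    threshold: float = 0.5,
) -> MetricsReport:
    """Evaluate a test set image by image and pooled.

    Pooling sums the confusion counts over all images and concatenates
    the in-FOV scores for the pooled curve areas (both aggregations are
    reported because either is a defensible way to summarise a set).
    """
    if fovs is None:
        fovs = [None] * len(ids)
    rows = []
    pooled_counts = ConfusionCounts(0, 0, 0, 0)
    pooled_scores, pooled_truth = [], []
    for sid, s, t, f in zip(ids, scores, truths, fovs):
        row = {"id": sid, **evaluate(s, t, f, threshold=threshold)}
        rows.append(row)
        pooled_counts = pooled_counts + ConfusionCounts(row["tp"], row["fp"], row["tn"], row["fn"])
        pooled_scores.append(_select(s, f))
        pooled_truth.append(_select(t, f))
    se, sp, acc = summary(pooled_counts)
    ps = np.concatenate(pooled_scores)
    pt = np.concatenate(pooled_truth)
    _, auc_roc = roc_curve_auc(ps, pt)
    _, auc_pr = pr_curve_auc(ps, pt)
    pooled = {
        "n_images": len(rows),
        "tp": pooled_counts.tp, "fp": pooled_counts.fp,
        "tn": pooled_counts.tn, "fn": pooled_counts.fn,
        "se": se, "sp": sp, "acc": acc,
        "fpr": 1.0 - sp if not math.isnan(sp) else math.nan,
        "auc_roc": auc_roc, "auc_pr": auc_pr,
    }
    return MetricsReport(per_image=pd.DataFrame(rows), pooled=pooled)
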