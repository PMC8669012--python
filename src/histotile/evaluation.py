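"""Accuracy reports, ROC/AUC and per-tile heatmaps.

"By class" accuracy is per-class recall; the positive class for ROC is
squamous (S).  AUC uses the Mann-Whitney identity (ties count one half),
which equals the trapezoidal integral of the threshold-sweep ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .classifier import TilePrediction

POSITIVE_CLASS = "S"


@dataclass
class EvalReport:
    level: str  # "tile" | "slide"
    strategy: dict = field(default_factory=dict)
    overall_accuracy: float = 0.0
    per_class_accuracy: dict[str, float] = field(default_factory=dict)
    n: dict[str, int] = field(default_factory=dict)


@dataclass
class RocCurve:
    points: list[tuple[float, float]]  # (FPR, TPR) from high to low threshold
    auc: float


def accuracy_report(
    predicted: list[str],
    truth: list[str],
    level: str = "tile",
    strategy: dict | None = None,
) -> EvalReport:
    """Overall accuracy plus per-class recall, mirroring a two-class table row."""
    if not predicted:
        raise ValueError("empty predictions")
    if len(predicted) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    overall = float(np.mean(pred == true))
    per_class: dict[str, float] = {}
    counts: dict[str, int] = {}
    for cls in sorted(set(true)):
        sel = true == cls
        counts[cls] = int(sel.sum())
        per_class[cls] = float(np.mean(pred[sel] == cls))
    return EvalReport(
        level=level,
        strategy=strategy or {},
        overall_accuracy=overall,
        per_class_accuracy=per_class,
        n=counts,
    )


def roc_auc(scores, labels) -> RocCurve:
    """ROC by threshold sweep; AUC by rank statistic (S is positive).

    AUC equals the probability that a random S item outscores a random NS
    item, with ties counted one half.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray([1 if lab == POSITIVE_CLASS else 0 for lab in labels])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = _sk_roc_curve(y, s)
    points = list(zip(fpr.tolist(), tpr.tolist()))
    return RocCurve(points=points, auc=float(auc))


def render_heatmap(
    preds: list[TilePrediction],
    n_rows: int,
    n_cols: int,
    selected: set[tuple[int, int]] | None = None,
    block_px: int = 8,
    out_path: str | Path | None = None,
) -> np.ndarray:
    """Per-tile color blocks: red ~ p_S for S tiles, green ~ p_NS for NS tiles.

    Grid positions without a prediction, or outside ``selected`` when given,
    are grey (background-filtered or gated-out tiles).  Returns the uint8
    image, additionally written as PNG when ``out_path`` is given.
    """
    grey = np.array([128, 128, 128], dtype=np.uint8)
    img = np.tile(grey, (n_rows * block_px, n_cols * block_px, 1))
    for p in preds:
        if selected is not None and (p.row, p.col) not in selected:
            continue
        if p.label == "S":
            color = np.array([int(round(255 * p.p_s)), 0, 0], dtype=np.uint8)
        else:
            color = np.array([0, int(round(255 * p.p_ns)), 0], dtype=np.uint8)
        r0, c0 = p.row * block_px, p.col * block_px
        img[r0:r0 + block_px, c0:c0 + block_px] = color
    if out_path is not None:
        from . import io as htio

        htio.write_image(out_path, img)
    return img
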