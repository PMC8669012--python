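"""Confidence thresholding, spatial filter-kernel re-estimation and slide calls.

Three inference-time strategies over per-tile probability pairs:

* grid-searched per-class confidence thresholds that drop low-confidence tiles;
* a logistic-regression "filter kernel" that re-scores each tile from its own
  probability and the label distribution of its 8-connected neighbours;
* slide-level aggregation by majority vote or max pooling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .classifier import TilePrediction

GRID_VALUES = [round(0.5 + 0.05 * k, 2) for k in range(10)]  # 0.5 .. 0.95
MIN_RETAINED_FRACTION = 0.05
NEIGHBOR_OFFSETS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                    if (dr, dc) != (0, 0)]


@dataclass
class ThresholdPair:
    t_ns: float
    t_s: float

    def __post_init__(self) -> None:
        for v in (self.t_ns, self.t_s):
            if not (0.5 <= v < 1.0):
                raise ValueError(f"thresholds must lie in [0.5, 1), got {v}")

    def to_dict(self) -> dict:
        return {"t_ns": self.t_ns, "t_s": self.t_s}


@dataclass
class SlideCall:
    slide_id: str
    method: str  # "majority" | "maxpool"
    call: str  # "NS" | "S"
    score: float  # majority: fraction of retained tiles voting S; maxpool: max p_S
    n_retained: int
    fallback_used: bool = False


class KernelFilterModel:
    """Logistic regression over (own p_S, neighbour S-fraction, missing fraction)."""

    feature_names = ("p_s", "neighbor_s_fraction", "missing_fraction")

    def __init__(self, coefficients: np.ndarray, intercept: float):
        self.coefficients = np.asarray(coefficients, dtype=np.float64).reshape(3)
        self.intercept = float(intercept)

    def predict_p_s(self, features: np.ndarray) -> np.ndarray:
        z = np.asarray(features, dtype=np.float64) @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "features": list(self.feature_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KernelFilterModel":
        return cls(np.asarray(d["coefficients"]), d["intercept"])


def _tile_is_correct(pred: TilePrediction, truth: dict[str, str]) -> bool:
    return pred.label == truth[pred.slide_id]


def apply_thresholds(
    preds: list[TilePrediction], thr: ThresholdPair
) -> list[TilePrediction]:
    """Keep NS-labelled tiles with p_NS >= t_NS and S-labelled with p_S >= t_S."""
    return [
        p for p in preds
        if (p.p_ns >= thr.t_ns if p.label == "NS" else p.p_s >= thr.t_s)
    ]


def grid_search_thresholds(
    preds: list[TilePrediction],
    slide_truth: dict[str, str],
    grid_step: float = 0.05,
    min_retained_fraction: float = MIN_RETAINED_FRACTION,
) -> ThresholdPair:
    """Exhaustive search of (t_NS, t_S) maximizing retained-tile accuracy.

    Candidates span {0.5, 0.5+step, ...} x same, below 1.  Pairs retaining
    fewer than ``min_retained_fraction`` of tiles are infeasible.  Ties break
    toward lower thresholds (ascending lexicographic scan, strict improvement).
    """
    if not preds:
        raise ValueError("no predictions supplied")
    values = [round(0.5 + grid_step * k, 10) for k in
              range(int(np.ceil((1.0 - 0.5) / grid_step)))]
    values = [v for v in values if v < 1.0]
    n_total = len(preds)
    best: tuple[float, ThresholdPair] | None = None
    for t_ns, t_s in itertools.product(values, values):
        pair = ThresholdPair(t_ns, t_s)
        retained = apply_thresholds(preds, pair)
        if len(retained) < min_retained_fraction * n_total:
            continue
        correct = sum(_tile_is_correct(p, slide_truth) for p in retained)
        acc = correct / len(retained)
        if best is None or acc > best[0]:
            best = (acc, pair)
    if best is None:
        raise ValueError("no feasible threshold pair retains enough tiles")
    return best[1]


def neighbor_label_distribution(
    grid_preds: dict[tuple[int, int], TilePrediction], address: tuple[int, int]
) -> np.ndarray:
    """Features (own p_S, S-fraction of valid neighbours, fraction missing).

    Absent/unkept neighbour positions are excluded from the label fraction's
    denominator; an isolated tile falls back to its own label's indicator.
    """
    if address not in grid_preds:
        raise KeyError(f"tile {address} not present in grid predictions")
    own = grid_preds[address]
    r, c = address
    neighbors = [grid_preds[(r + dr, c + dc)] for dr, dc in NEIGHBOR_OFFSETS
                 if (r + dr, c + dc) in grid_preds]
    n_valid = len(neighbors)
    if n_valid == 0:
        frac_s = 1.0 if own.label == "S" else 0.0
    else:
        frac_s = sum(p.label == "S" for p in neighbors) / n_valid
    missing = (8 - n_valid) / 8.0
    return np.array([own.p_s, frac_s, missing])


def _features_by_slide(preds: list[TilePrediction]) -> np.ndarray:
    by_slide: dict[str, dict[tuple[int, int], TilePrediction]] = {}
    for p in preds:
        by_slide.setdefault(p.slide_id, {})[(p.row, p.col)] = p
    return np.array([
        neighbor_label_distribution(by_slide[p.slide_id], (p.row, p.col))
        for p in preds
    ])


def fit_filter_kernel(
    preds: list[TilePrediction], slide_truth: dict[str, str]
) -> KernelFilterModel:
    """Fit the kernel's logistic regression, tile target = slide's true class."""
    if not preds:
        raise ValueError("no predictions supplied")
    x = _features_by_slide(preds)
    y = np.array([1 if slide_truth[p.slide_id] == "S" else 0 for p in preds])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit the filter kernel")
    # effectively unpenalized maximum likelihood
    lr = LogisticRegression(C=1e10, solver="lbfgs", max_iter=2000)
    lr.fit(x, y)
    return KernelFilterModel(lr.coef_[0], lr.intercept_[0])


def apply_filter_kernel(
    model: KernelFilterModel, preds: list[TilePrediction]
) -> list[TilePrediction]:
    """Replace every probability pair in one simultaneous pass.

    Features are computed from the input labels only, so the update is not
    iterative relaxation.
    """
    if not preds:
        return []
    x = _features_by_slide(preds)
    p_s = model.predict_p_s(x)
    return [
        TilePrediction(p.slide_id, p.row, p.col, 1.0 - float(ps), float(ps))
        for p, ps in zip(preds, p_s)
    ]


def _resolve_retained(
    preds: list[TilePrediction], retained: list[TilePrediction] | None
) -> tuple[list[TilePrediction], bool]:
    if retained:
        return retained, False
    # zero retained tiles: fall back to the unthresholded predictions
    if not preds:
        raise ValueError("no predictions for slide")
    return preds, True


def call_majority(
    preds: list[TilePrediction], retained: list[TilePrediction] | None = None
) -> SlideCall:
    """Most frequent retained label; tie -> larger mean confidence, then NS."""
    tiles, fallback = _resolve_retained(preds, retained if retained is not None else preds)
    sid = tiles[0].slide_id
    s_tiles = [p for p in tiles if p.label == "S"]
    ns_tiles = [p for p in tiles if p.label == "NS"]
    if len(s_tiles) > len(ns_tiles):
        call = "S"
    elif len(ns_tiles) > len(s_tiles):
        call = "NS"
    else:
        mean_s = np.mean([p.confidence for p in s_tiles]) if s_tiles else 0.0
        mean_ns = np.mean([p.confidence for p in ns_tiles]) if ns_tiles else 0.0
        call = "S" if mean_s > mean_ns else "NS"
    score = len(s_tiles) / len(tiles)
    return SlideCall(sid, "majority", call, float(score), len(tiles), fallback)


def call_maxpool(
    preds: list[TilePrediction], retained: list[TilePrediction] | None = None
) -> SlideCall:
    """Label of the single most confident retained tile; tie -> NS."""
    tiles, fallback = _resolve_retained(preds, retained if retained is not None else preds)
    sid = tiles[0].slide_id
    max_conf = max(p.confidence for p in tiles)
    top = [p for p in tiles if p.confidence == max_conf]
    call = "NS" if any(p.label == "NS" for p in top) else "S"
    score = max(p.p_s for p in tiles)
    return SlideCall(sid, "maxpool", call, float(score), len(tiles), fallback)
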