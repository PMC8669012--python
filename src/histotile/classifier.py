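"""Slide-grouped splitting, augmentation, weighted loss and tile classification.

Training follows a fixed reference schedule: Adam (momentum 0.9, epsilon 1e-7),
initial learning rate 0.001 decayed by 0.9 every 5 epochs, batch size 100,
and a cross-entropy loss multiplied by 1.5 for currently misclassified
examples (both error directions penalized equally).  The backbone is
pluggable; the default ``tiny_cnn`` trains on CPU in seconds at test scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from skimage.transform import resize

from .nets import BACKBONES, Adam, TinyCnn, softmax
from .synthetic import CLASSES, CohortManifest
from .tiling import SlideImage, TileGrid

LABEL_INDEX = {"NS": 0, "S": 1}
PROB_CLAMP = 1e-12


@dataclass
class SplitAssignment:
    """slide_id -> one of train/val/test, grouped at slide level."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def slides(self, part: str) -> list[str]:
        return sorted(s for s, p in self.assignment.items() if p == part)


@dataclass
class TrainConfig:
    epochs: int = 100
    lr0: float = 0.001
    lr_decay: float = 0.9
    decay_every: int = 5
    momentum: float = 0.9
    adam_epsilon: float = 1e-7
    batch_size: int = 100
    loss_weight: float = 1.5
    seed: int = 0
    backbone: str = "tiny_cnn"
    augment: bool = True

    def validate(self) -> None:
        if min(self.epochs, self.batch_size, self.decay_every) < 1:
            raise ValueError("epochs, batch_size and decay_every must be >= 1")
        if min(self.lr0, self.lr_decay, self.loss_weight) <= 0:
            raise ValueError("rates and loss_weight must be > 0")
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")


@dataclass
class TilePrediction:
    slide_id: str
    row: int
    col: int
    p_ns: float
    p_s: float
    label: str = field(init=False)
    confidence: float = field(init=False)

    def __post_init__(self) -> None:
        if abs(self.p_ns + self.p_s - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")
        # tie at 0.5 -> NS
        self.label = "S" if self.p_s > self.p_ns else "NS"
        self.confidence = max(self.p_ns, self.p_s)

    @property
    def address(self) -> tuple[str, int, int]:
        return (self.slide_id, self.row, self.col)


def split_slides(
    manifest: CohortManifest,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Stratified slide-level train/val/test split.

    Per class: floor(f_train*n) train and floor(f_val*n) validation slides,
    remainder to test (132 balanced slides at 60/20/20 give 78/26/28).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    by_class: dict[str, list[str]] = {c: [] for c in CLASSES}
    for rec in manifest.records:
        by_class.setdefault(rec["class"], []).append(rec["slide_id"])
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for cls in sorted(by_class):
        ids = sorted(by_class[cls])
        if len(ids) < 5:
            raise ValueError(f"need >= 5 slides per class, class {cls} has {len(ids)}")
        rng.shuffle(ids)
        n = len(ids)
        n_train = int(np.floor(fractions[0] * n))
        n_val = int(np.floor(fractions[1] * n))
        for sid in ids[:n_train]:
            assignment[sid] = "train"
        for sid in ids[n_train:n_train + n_val]:
            assignment[sid] = "val"
        for sid in ids[n_train + n_val:]:
            assignment[sid] = "test"
    return SplitAssignment(assignment=assignment, fractions=fractions, seed=seed)


def augment_tile(tile_pixels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random flips and 90-degree rotations; preserves the pixel multiset."""
    t = np.asarray(tile_pixels)
    if t.shape[0] != t.shape[1]:
        raise ValueError("augment_tile expects a square tile")
    if rng.random() < 0.5:
        t = t[:, ::-1]
    if rng.random() < 0.5:
        t = t[::-1, :]
    t = np.rot90(t, k=int(rng.integers(0, 4)))
    return np.ascontiguousarray(t)


def weighted_loss(
    p: Sequence[float], y: str, w: float = 1.5, reduce_clamp: float = PROB_CLAMP
) -> float:
    """Cross-entropy -log p_y, times ``w`` when argmax(p) disagrees with y."""
    p = np.asarray(p, dtype=np.float64)
    yi = LABEL_INDEX[y]
    p_y = max(float(p[yi]), reduce_clamp)
    loss = -np.log(p_y)
    predicted = int(np.argmax(p))  # tie -> index 0 = NS, consistent with labels
    if predicted != yi:
        loss *= w
    return float(loss)


def prepare_tiles(
    slide: SlideImage, grid: TileGrid, input_px: int = TinyCnn.input_px
) -> tuple[np.ndarray, list[tuple[str, int, int]]]:
    """Extract kept tiles as unit-scale rasters resized to the model input size.

    Returns (N, input_px, input_px, 3) array and the tile addresses.
    """
    unit = slide.unit_pixels()
    arrays, addrs = [], []
    for t in grid.kept_tiles():
        tile = unit[t.y0:t.y1, t.x0:t.x1]
        small = resize(tile, (input_px, input_px), anti_aliasing=True,
                       preserve_range=True)
        arrays.append(small)
        addrs.append((t.slide_id, t.row, t.col))
    x = np.stack(arrays) if arrays else np.zeros((0, input_px, input_px, 3))
    return x, addrs


class TrainedModel:
    """A fitted backbone plus its config and training history."""

    def __init__(self, net, config: TrainConfig,
                 history: dict[str, list[float]]):
        self.net = net
        self.config = config
        self.history = history

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """x: (N, input_px, input_px, 3) unit-scale tiles -> (N, 2) probabilities."""
        if x.shape[0] == 0:
            return np.zeros((0, 2))
        out = [self.net.predict_proba(x[i:i + batch_size])
               for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(out, axis=0)


def _batch_loss_and_grad(net, xb, yb, w):
    logits = net.forward(xb)
    p = softmax(logits)
    n = xb.shape[0]
    onehot = np.zeros_like(p)
    onehot[np.arange(n), yb] = 1.0
    wrong = (p.argmax(axis=1) != yb)
    weights = np.where(wrong, w, 1.0)
    p_y = np.clip(p[np.arange(n), yb], PROB_CLAMP, None)
    loss = float(np.mean(weights * -np.log(p_y)))
    dlogits = (p - onehot) * weights[:, None] / n
    acc = float(np.mean(~wrong))
    return loss, acc, dlogits


def train_classifier(
    x_train: np.ndarray,
    y_train: Iterable[str],
    config: TrainConfig,
    x_val: np.ndarray | None = None,
    y_val: Iterable[str] | None = None,
) -> TrainedModel:
    """Train the configured backbone on labelled tiles.

    ``x_train``: (N, input_px, input_px, 3) unit-scale rasters;
    ``y_train``: class names ("NS"/"S").  Records per-epoch loss/accuracy
    curves (and validation curves when a validation set is given).
    """
    config.validate()
    y = np.array([LABEL_INDEX[c] for c in y_train])
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    net = BACKBONES[config.backbone](seed=config.seed)
    if x_train.shape[1] != net.input_px:
        raise ValueError(
            f"tiles must be resized to {net.input_px} px (got {x_train.shape[1]})"
        )
    opt = Adam(net, lr=config.lr0, beta1=config.momentum, eps=config.adam_epsilon)
    rng = np.random.default_rng(config.seed)
    n = x_train.shape[0]
    history: dict[str, list[float]] = {"loss": [], "accuracy": [],
                                       "val_loss": [], "val_accuracy": []}
    yv = None
    if x_val is not None and y_val is not None:
        yv = np.array([LABEL_INDEX[c] for c in y_val])

    for epoch in range(config.epochs):
        opt.lr = config.lr0 * config.lr_decay ** (epoch // config.decay_every)
        order = rng.permutation(n)
        losses, accs = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = x_train[idx]
            if config.augment:
                xb = np.stack([augment_tile(t, rng) for t in xb])
            loss, acc, dlogits = _batch_loss_and_grad(net, xb, y[idx], config.loss_weight)
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
            accs.append(acc)
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(float(np.mean(accs)))
        if yv is not None:
            vloss, vacc, _ = _batch_loss_and_grad(net, x_val, yv, config.loss_weight)
            history["val_loss"].append(vloss)
            history["val_accuracy"].append(vacc)
    return TrainedModel(net, config, history)


def predict_tiles(
    model: TrainedModel,
    x: np.ndarray,
    addresses: list[tuple[str, int, int]],
) -> list[TilePrediction]:
    """One probability pair per kept tile; deterministic and batch-invariant."""
    if x.shape[0] != len(addresses):
        raise ValueError("tile array and address list lengths differ")
    probs = model.predict_proba(x)
    preds = []
    for (sid, row, col), pr in zip(addresses, probs):
        p_ns, p_s = float(pr[0]), float(pr[1])
        total = p_ns + p_s
        preds.append(TilePrediction(sid, row, col, p_ns / total, p_s / total))
    return preds
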