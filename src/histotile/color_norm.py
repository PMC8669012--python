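"""Reinhard color normalization in Lab space and unit-range scaling.

Per-channel mean/sd are matched between a source image and a reference via a
linear transform applied in Lab coordinates, then converted back to RGB and
clipped.  Statistics are computed over tissue (non-white) pixels when a mask
is supplied, so the white background does not dominate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

MIN_MASK_PIXELS = 100


@dataclass
class ChannelStats:
    """Per-channel mean and standard deviation in Lab space."""

    mean: np.ndarray  # shape (3,)
    sd: np.ndarray  # shape (3,)
    space: str = "lab"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64).reshape(3)
        self.sd = np.asarray(self.sd, dtype=np.float64).reshape(3)
        if np.any(self.sd <= 0):
            raise ValueError("zero variance channel: sd components must be > 0")

    def to_dict(self) -> dict:
        return {"space": self.space, "mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelStats":
        return cls(mean=d["mean"], sd=d["sd"], space=d.get("space", "lab"))


def _as_unit_rgb(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB image, got shape {img.shape}")
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(np.float64) / 255.0
    return img.astype(np.float64)


def compute_channel_stats(
    image: np.ndarray, tissue_mask: np.ndarray | None = None
) -> ChannelStats:
    """Lab-space per-channel mean/sd over masked (tissue) pixels.

    Raises on a constant channel ("zero variance channel") or when the mask
    selects fewer than ``MIN_MASK_PIXELS`` pixels.
    """
    rgb = _as_unit_rgb(image)
    lab = skcolor.rgb2lab(rgb)
    if tissue_mask is not None:
        mask = np.asarray(tissue_mask, dtype=bool)
        if mask.shape != rgb.shape[:2]:
            raise ValueError("tissue_mask shape does not match image")
        if mask.sum() < MIN_MASK_PIXELS:
            raise ValueError(
                f"mask selects {int(mask.sum())} pixels; need >= {MIN_MASK_PIXELS}"
            )
        sel = lab[mask]
    else:
        sel = lab.reshape(-1, 3)
    mean = sel.mean(axis=0)
    sd = sel.std(axis=0)
    if np.any(sd <= 1e-8):  # constant up to float summation noise
        raise ValueError("zero variance channel")
    return ChannelStats(mean=mean, sd=sd)


def reinhard_normalize(
    image: np.ndarray, source: ChannelStats, target: ChannelStats
) -> np.ndarray:
    """Match Lab channel mean/sd of ``image`` to ``target``.

    out_c = (in_c - source.mean_c) * target.sd_c / source.sd_c + target.mean_c,
    applied per Lab channel, then converted back to RGB and clipped to [0, 1].
    Returns a float image in [0, 1].
    """
    rgb = _as_unit_rgb(image)
    lab = skcolor.rgb2lab(rgb)
    scale = target.sd / source.sd
    lab = (lab - source.mean) * scale + target.mean
    out = skcolor.lab2rgb(lab)
    return np.clip(out, 0.0, 1.0)


def to_unit_range(image: np.ndarray) -> np.ndarray:
    """Scale an 8-bit raster to floats in [0, 1] by dividing by 255."""
    img = np.asarray(image)
    if not np.issubdtype(img.dtype, np.integer):
        raise ValueError("to_unit_range expects an integer (8-bit) raster")
    return img.astype(np.float64) / 255.0
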