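"""Seeded virtual-biopsy generator.

Produces slides that look like small tissue fragments on a white background:
each fragment carries a common stroma texture plus a tumour region whose
texture depends on the slide class — high-frequency speckle for squamous (S),
smooth gland-like rings for non-squamous (NS).  Texture parameters live in
``TEXTURE_PARAMS`` and are chosen for learnability by a small CNN, not for
biological realism.  The same spec and seed always yield bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .tiling import SlideImage, WHITE_LEVEL

CLASSES = ("NS", "S")

#: All texture parameters in one place (unit-scale RGB / grayscale amplitudes).
TEXTURE_PARAMS = {
    "background_value": 0.98,  # above the 0.94 white rule
    "stroma_rgb": (0.91, 0.76, 0.83),
    "stroma_noise_amp": 0.04,
    "stroma_noise_sigma": 12.0,
    "tumour_rgb": (0.58, 0.40, 0.63),
    # S: band-limited speckle (keratin-like granularity)
    "speckle_sigma": 6.0,
    "speckle_amp": 0.25,
    # NS: smooth concentric rings (gland-like)
    "ring_period_px": 80.0,
    "ring_amp": 0.20,
}


@dataclass
class SyntheticSlideSpec:
    """Parameters of one virtual biopsy slide."""

    slide_id: str
    true_class: str  # "NS" | "S"
    width_px: int = 1320
    height_px: int = 1320
    microns_per_pixel: float = 0.5
    n_fragments: int = 2
    tumour_fraction: float = 0.8
    stain_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.true_class not in CLASSES:
            raise ValueError(f"true_class must be one of {CLASSES}, got {self.true_class!r}")
        if self.width_px < 3 * 220 or self.height_px < 3 * 220:
            raise ValueError(
                "width_px/height_px must be >= 660 so a 3x3 tile grid exists; "
                f"got {self.width_px}x{self.height_px}"
            )
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be >= 1")
        if not (0.0 < self.tumour_fraction <= 1.0):
            raise ValueError("tumour_fraction must be in (0, 1]")
        if len(self.stain_shift) != 3 or any(abs(s) > 0.2 for s in self.stain_shift):
            raise ValueError("stain_shift must be 3 per-channel offsets in [-0.2, 0.2]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class AnnotationSet:
    """Tumour-region polygons of one slide, pixel coordinates, origin top-left."""

    slide_id: str
    polygons: list[np.ndarray]  # each (n_vertices, 2) array of (x, y)


@dataclass
class CohortManifest:
    records: list[dict] = field(default_factory=list)
    # record keys: slide_id, path, class, annotation_path

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r["class"]] = counts.get(r["class"], 0) + 1
        return counts

    def validate(self) -> None:
        ids = [r["slide_id"] for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate slide_id in manifest")


def _star_polygon(rng: np.random.Generator, cx: float, cy: float, radius: float,
                  n_vertices: int = 48) -> np.ndarray:
    """Star-convex blob: radius modulated by a few random low-order harmonics."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = np.ones_like(theta)
    for k in (2, 3, 5):
        r += 0.08 * rng.uniform(-1, 1) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    r = np.clip(r, 0.6, 1.4) * radius
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def _scale_polygon(poly: np.ndarray, factor: float) -> np.ndarray:
    """Scale about the vertex centroid; area scales by factor**2."""
    c = poly.mean(axis=0)
    return (poly - c) * factor + c


def _place_fragment_centers(
    rng: np.random.Generator, w: int, h: int, n: int, radius: float
) -> list[tuple[float, float]]:
    """Centers with a margin from the border and pairwise separation > 2.9 R."""
    for _ in range(8):  # shrink and retry if the packing is too tight
        margin = 1.45 * radius
        if 2 * margin < w and 2 * margin < h:
            centers: list[tuple[float, float]] = []
            for _ in range(5000):
                if len(centers) == n:
                    return centers, radius
                cx = rng.uniform(margin, w - margin)
                cy = rng.uniform(margin, h - margin)
                if all((cx - x) ** 2 + (cy - y) ** 2 > (2.9 * radius) ** 2
                       for x, y in centers):
                    centers.append((cx, cy))
            if len(centers) == n:
                return centers, radius
        radius *= 0.85
    raise ValueError(
        f"could not place {n} disjoint fragments in a {w}x{h} image"
    )


def _rasterize(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Gaussian-filtered white noise renormalized to unit variance."""
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = z.std()
    return z / sd if sd > 0 else z


def texture_stat(tile_gray: np.ndarray, lag: int = 2) -> float:
    """Fixed texture statistic used for class-separability checks.

    Mean absolute grayscale difference between pixels ``lag`` apart
    (horizontal and vertical pooled).  High for speckle, low for smooth rings.
    """
    g = np.asarray(tile_gray, dtype=np.float64)
    dx = np.abs(g[:, lag:] - g[:, :-lag])
    dy = np.abs(g[lag:, :] - g[:-lag, :])
    return float((dx.sum() + dy.sum()) / (dx.size + dy.size))


def generate_slide(spec: SyntheticSlideSpec) -> tuple[SlideImage, AnnotationSet]:
    """Render one virtual biopsy and its tumour annotation polygons."""
    spec.validate()
    p = TEXTURE_PARAMS
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    shape = (h, w)

    frag_radius = min(w, h) / (2.8 + 1.7 * spec.n_fragments**0.5)
    centers, frag_radius = _place_fragment_centers(
        rng, w, h, spec.n_fragments, frag_radius
    )
    fragments = [_star_polygon(rng, cx, cy, frag_radius) for cx, cy in centers]
    tumours = [_scale_polygon(f, np.sqrt(spec.tumour_fraction)) for f in fragments]

    tissue_mask = np.zeros(shape, dtype=bool)
    for f in fragments:
        tissue_mask |= _rasterize(f, shape)
    tumour_mask = np.zeros(shape, dtype=bool)
    for t in tumours:
        tumour_mask |= _rasterize(t, shape)
    tumour_mask &= tissue_mask
    stroma_mask = tissue_mask & ~tumour_mask

    img = np.full((h, w, 3), p["background_value"], dtype=np.float64)

    stroma_tex = p["stroma_noise_amp"] * _smooth_noise(rng, shape, p["stroma_noise_sigma"])
    for c in range(3):
        img[..., c][stroma_mask] = p["stroma_rgb"][c] + stroma_tex[stroma_mask]

    if spec.true_class == "S":
        tex = p["speckle_amp"] * _smooth_noise(rng, shape, p["speckle_sigma"])
    else:
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        tex = np.zeros(shape)
        for cx, cy in centers:
            jx = cx + rng.uniform(-0.2, 0.2) * frag_radius
            jy = cy + rng.uniform(-0.2, 0.2) * frag_radius
            d = np.hypot(xx - jx, yy - jy)
            tex += np.sin(2.0 * np.pi * d / p["ring_period_px"] + rng.uniform(0, 2 * np.pi))
        tex *= p["ring_amp"] / max(1.0, spec.n_fragments**0.5)
    for c in range(3):
        img[..., c][tumour_mask] = p["tumour_rgb"][c] + tex[tumour_mask]

    for c in range(3):
        img[..., c][tissue_mask] += spec.stain_shift[c]
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=(h, w, 3))
        img[tissue_mask] += noise[tissue_mask]
    img = np.clip(img, 0.0, 1.0)
    pixels = np.round(img * 255.0).astype(np.uint8)

    slide = SlideImage(
        slide_id=spec.slide_id,
        pixels=pixels,
        microns_per_pixel=spec.microns_per_pixel,
        true_class=spec.true_class,
    )
    return slide, AnnotationSet(slide_id=spec.slide_id, polygons=tumours)


def tissue_mask_of(slide: SlideImage, white_level: float = WHITE_LEVEL) -> np.ndarray:
    """Non-white pixels of a slide (any channel below the white level)."""
    unit = slide.unit_pixels()
    return ~np.all(unit >= white_level, axis=2)


def derive_slide_seed(cohort_seed: int, index: int) -> int:
    """Deterministic per-slide seed from the cohort seed."""
    ss = np.random.SeedSequence(entropy=cohort_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0])


def generate_cohort(
    n_per_class: int,
    template: SyntheticSlideSpec,
    seed: int,
    out_dir: str | Path,
) -> CohortManifest:
    """Write a balanced cohort of slides (PNG), GeoJSON annotations and a manifest.

    The template's ``stain_shift`` is interpreted as per-channel bounds: each
    slide draws its own shift uniformly from [-bound, +bound] per channel.
    Per-slide seeds are derived deterministically from ``seed``.
    """
    from . import io as htio  # local import to avoid cycle

    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bounds = np.abs(np.asarray(template.stain_shift, dtype=np.float64))

    manifest = CohortManifest()
    idx = 0
    for cls in CLASSES:
        for i in range(n_per_class):
            slide_seed = derive_slide_seed(seed, idx)
            rng = np.random.default_rng(derive_slide_seed(seed, idx + 100000))
            shift = tuple(rng.uniform(-bounds, bounds))
            sid = f"{cls}{i:03d}"
            spec = replace(
                template,
                slide_id=sid,
                true_class=cls,
                stain_shift=shift,
                seed=slide_seed,
            )
            slide, anns = generate_slide(spec)
            img_path = out / f"{sid}.png"
            ann_path = out / f"{sid}.geojson"
            htio.write_image(img_path, slide.pixels)
            htio.write_annotations(ann_path, anns)
            manifest.records.append(
                {
                    "slide_id": sid,
                    "path": str(img_path),
                    "class": cls,
                    "annotation_path": str(ann_path),
                }
            )
            idx += 1
    manifest.validate()
    htio.write_manifest(out / "manifest.tsv", manifest)
    (out / "cohort.json").write_text(
        json.dumps({"seed": seed, "n_per_class": n_per_class}, indent=2)
    )
    return manifest
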