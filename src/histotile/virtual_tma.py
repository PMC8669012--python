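"""Virtual tissue-microarray cores from tumour annotations.

Each annotation polygon yields one circular core of physical radius 500 um
around its centroid; tiles whose centers fall inside any core (and that
survived background filtering) form the TMA-restricted tile set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .synthetic import AnnotationSet
from .tiling import TileGrid

TMA_RADIUS_UM = 500.0


@dataclass
class TmaRegion:
    slide_id: str
    center: tuple[float, float]  # (x, y) pixels
    radius_px: float

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius_px must be > 0")


def annotation_centroid(polygons) -> tuple[float, float]:
    """Area-weighted centroid of one or more pixel-coordinate rings."""
    polys = []
    for ring in polygons:
        poly = Polygon(np.asarray(ring, dtype=np.float64))
        if not poly.is_valid:
            poly = poly.buffer(0)
        polys.append(poly)
    union = unary_union(polys)
    if union.area <= 0:
        raise ValueError("degenerate (zero-area) annotation polygon")
    c = union.centroid
    return (float(c.x), float(c.y))


def tma_regions(
    anns: AnnotationSet,
    microns_per_pixel: float,
    radius_um: float = TMA_RADIUS_UM,
) -> list[TmaRegion]:
    """One core per annotation polygon, radius radius_um / microns_per_pixel."""
    if microns_per_pixel <= 0:
        raise ValueError("microns_per_pixel must be > 0")
    radius_px = radius_um / microns_per_pixel
    return [
        TmaRegion(anns.slide_id, annotation_centroid([poly]), radius_px)
        for poly in anns.polygons
    ]


def select_tma_tiles(grid: TileGrid, regions: list[TmaRegion]) -> TileGrid:
    """Subset of kept tiles whose center lies within any core circle."""
    if not regions:
        raise ValueError("no TMA regions supplied")
    for reg in regions:
        if reg.slide_id != grid.slide_id:
            raise ValueError(
                f"region slide {reg.slide_id!r} does not match grid {grid.slide_id!r}"
            )
    selected = []
    for t in grid.tiles:
        if not t.kept:
            continue
        cx, cy = t.center
        for reg in regions:
            dx, dy = cx - reg.center[0], cy - reg.center[1]
            if dx * dx + dy * dy <= reg.radius_px**2:
                selected.append(t)
                break
    return TileGrid(grid.slide_id, grid.n_rows, grid.n_cols, grid.tile_px, selected)
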