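"""Fixed-grid tiling of slide rasters and white-background tile removal.

Slides are partitioned into non-overlapping ``tile_px`` x ``tile_px`` squares
anchored at the image origin; trailing partial strips are discarded.  A tile is
dropped when more than ``max_white`` of its pixels are "white", i.e. all three
channels at or above ``white_level`` on the unit scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

TILE_PX = 220
WHITE_LEVEL = 0.94
MAX_WHITE = 2.0 / 3.0

#: Default physical scale: 0.5 micron per pixel (20x magnification).
MICRONS_PER_PIXEL = 0.5


@dataclass
class SlideImage:
    """An RGB slide raster with physical scale and optional ground truth."""

    slide_id: str
    pixels: np.ndarray  # H x W x 3, uint8 or float in [0, 1]
    microns_per_pixel: float = MICRONS_PER_PIXEL
    true_class: Optional[str] = None  # "NS" | "S"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("empty image")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def unit_pixels(self) -> np.ndarray:
        """Pixels as float in [0, 1] regardless of storage dtype."""
        if np.issubdtype(self.pixels.dtype, np.integer):
            return self.pixels.astype(np.float64) / 255.0
        return self.pixels.astype(np.float64)


@dataclass
class Tile:
    """One grid cell. bbox is half-open: [x0, x1) x [y0, y1)."""

    slide_id: str
    row: int
    col: int
    x0: int
    y0: int
    x1: int
    y1: int
    white_fraction: Optional[float] = None
    kept: bool = True

    @property
    def center(self) -> tuple[float, float]:
        """(x, y) pixel center of the tile."""
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def pixels(self, slide: SlideImage) -> np.ndarray:
        return slide.pixels[self.y0:self.y1, self.x0:self.x1]


@dataclass
class TileGrid:
    slide_id: str
    n_rows: int
    n_cols: int
    tile_px: int
    tiles: list[Tile] = field(default_factory=list)

    def kept_tiles(self) -> list[Tile]:
        return [t for t in self.tiles if t.kept]

    def tile_at(self, row: int, col: int) -> Tile:
        return self.tiles[row * self.n_cols + col]


def build_tile_grid(slide: SlideImage, tile_px: int = TILE_PX) -> TileGrid:
    """Partition a slide into a floor(H/tile_px) x floor(W/tile_px) grid.

    Raises ``ValueError`` when the image is smaller than one tile.
    """
    h, w = slide.height, slide.width
    if h < tile_px or w < tile_px:
        raise ValueError(
            f"image {w}x{h} smaller than one tile; need at least "
            f"{tile_px}x{tile_px} pixels"
        )
    n_rows, n_cols = h // tile_px, w // tile_px
    tiles = [
        Tile(
            slide_id=slide.slide_id,
            row=r,
            col=c,
            x0=c * tile_px,
            y0=r * tile_px,
            x1=c * tile_px + tile_px,
            y1=r * tile_px + tile_px,
        )
        for r in range(n_rows)
        for c in range(n_cols)
    ]
    return TileGrid(slide.slide_id, n_rows, n_cols, tile_px, tiles)


def white_fraction(tile_pixels: np.ndarray, white_level: float = WHITE_LEVEL) -> float:
    """Fraction of pixels whose three channels all reach ``white_level``.

    Accepts 8-bit or unit-scale rasters; 8-bit values are compared on the
    unit scale (value / 255) so both encodings agree exactly.
    """
    px = np.asarray(tile_pixels)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"tile pixels must be HxWx3, got shape {px.shape}")
    if np.issubdtype(px.dtype, np.integer):
        px = px.astype(np.float64) / 255.0
    white = np.all(px >= white_level, axis=2)
    return float(white.mean())


def filter_tiles(
    grid: TileGrid,
    slide: SlideImage,
    max_white: float = MAX_WHITE,
    white_level: float = WHITE_LEVEL,
) -> TileGrid:
    """Mark tiles with *more than* ``max_white`` white background as not kept.

    A tile at exactly the threshold is kept.  Geometry is unchanged; a new
    grid is returned.
    """
    if grid.slide_id != slide.slide_id:
        raise ValueError(
            f"grid belongs to slide {grid.slide_id!r}, not {slide.slide_id!r}"
        )
    tiles = []
    for t in grid.tiles:
        wf = white_fraction(t.pixels(slide), white_level=white_level)
        tiles.append(replace(t, white_fraction=wf, kept=wf <= max_white))
    return TileGrid(grid.slide_id, grid.n_rows, grid.n_cols, grid.tile_px, tiles)
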