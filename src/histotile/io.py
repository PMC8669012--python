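"""Readers and writers for the pipeline's tabular and sidecar formats.

All tabular formats are TSV with a fixed header; round-trips are lossless.
Schema violations raise ``ValueError`` naming the missing column; malformed
rows are reported with their line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synthetic import AnnotationSet, CohortManifest
from .tiling import Tile, TileGrid

MANIFEST_COLUMNS = ["slide_id", "path", "class", "annotation_path"]
TILE_COLUMNS = ["slide_id", "row", "col", "x0", "y0", "x1", "y1", "white_fraction", "kept"]
PRED_COLUMNS = ["slide_id", "row", "col", "p_ns", "p_s", "label", "confidence"]
CALL_COLUMNS = ["slide_id", "method", "call", "score", "n_retained", "fallback_used"]


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


# ---------------------------------------------------------------- images

def write_image(path: str | Path, pixels: np.ndarray) -> None:
    path = Path(path)
    if pixels.dtype != np.uint8:
        pixels = np.round(np.clip(pixels, 0, 1) * 255).astype(np.uint8)
    iio.imwrite(path, pixels)


def read_image(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return arr[..., :3]


# ---------------------------------------------------------------- manifest

def write_manifest(path: str | Path, manifest: CohortManifest) -> None:
    df = pd.DataFrame(manifest.records, columns=MANIFEST_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> CohortManifest:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _check_columns(df, MANIFEST_COLUMNS, path)
    for i, row in df.iterrows():
        if row[MANIFEST_COLUMNS].isna().any():
            raise ValueError(f"{path}: malformed row at line {i + 2}")
    manifest = CohortManifest(records=df[MANIFEST_COLUMNS].to_dict("records"))
    manifest.validate()
    return manifest


# ---------------------------------------------------------------- tile tables

def write_tile_table(path: str | Path, grid: TileGrid) -> None:
    rows = [
        {
            "slide_id": t.slide_id,
            "row": t.row,
            "col": t.col,
            "x0": t.x0,
            "y0": t.y0,
            "x1": t.x1,
            "y1": t.y1,
            "white_fraction": t.white_fraction,
            "kept": int(t.kept),
        }
        for t in grid.tiles
    ]
    pd.DataFrame(rows, columns=TILE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tile_table(path: str | Path) -> TileGrid:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, TILE_COLUMNS, path)
    tiles = [
        Tile(
            slide_id=str(r.slide_id),
            row=int(r.row),
            col=int(r.col),
            x0=int(r.x0),
            y0=int(r.y0),
            x1=int(r.x1),
            y1=int(r.y1),
            white_fraction=None if pd.isna(r.white_fraction) else float(r.white_fraction),
            kept=bool(r.kept),
        )
        for r in df.itertuples()
    ]
    n_rows = max(t.row for t in tiles) + 1
    n_cols = max(t.col for t in tiles) + 1
    tile_px = tiles[0].x1 - tiles[0].x0
    return TileGrid(tiles[0].slide_id, n_rows, n_cols, tile_px, tiles)


# ---------------------------------------------------------------- predictions

def write_predictions(path: str | Path, preds) -> None:
    rows = [
        {
            "slide_id": p.slide_id,
            "row": p.row,
            "col": p.col,
            "p_ns": repr(float(p.p_ns)),
            "p_s": repr(float(p.p_s)),
            "label": p.label,
            "confidence": repr(float(p.confidence)),
        }
        for p in preds
    ]
    pd.DataFrame(rows, columns=PRED_COLUMNS).to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path):
    from .classifier import TilePrediction

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _check_columns(df, PRED_COLUMNS, path)
    return [
        TilePrediction(
            slide_id=str(r.slide_id),
            row=int(r.row),
            col=int(r.col),
            p_ns=float(r.p_ns),
            p_s=float(r.p_s),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------- slide calls

def write_calls(path: str | Path, calls) -> None:
    rows = [
        {
            "slide_id": c.slide_id,
            "method": c.method,
            "call": c.call,
            "score": repr(float(c.score)),
            "n_retained": c.n_retained,
            "fallback_used": int(c.fallback_used),
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path):
    from .postprocess import SlideCall

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _check_columns(df, CALL_COLUMNS, path)
    return [
        SlideCall(
            slide_id=str(r.slide_id),
            method=str(r.method),
            call=str(r.call),
            score=float(r.score),
            n_retained=int(r.n_retained),
            fallback_used=bool(r.fallback_used),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------- JSON sidecars

def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------- GeoJSON

def write_annotations(path: str | Path, anns: AnnotationSet) -> None:
    """QuPath-style GeoJSON FeatureCollection, pixel coordinates."""
    features = []
    for poly in anns.polygons:
        ring = [[float(x), float(y)] for x, y in poly]
        if ring and ring[0] != ring[-1]:
            ring = ring + [ring[0]]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"classification": {"name": "Tumor"}},
            }
        )
    obj = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"slide_id": anns.slide_id},
    }
    Path(path).write_text(json.dumps(obj) + "\n")


def read_annotations(path: str | Path, slide_id: str | None = None) -> AnnotationSet:
    obj = json.loads(Path(path).read_text())
    if obj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    sid = slide_id or obj.get("properties", {}).get("slide_id", Path(path).stem)
    polygons = []
    for feat in obj.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            continue
        ring = np.asarray(geom["coordinates"][0], dtype=np.float64)
        if len(ring) > 1 and np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
        polygons.append(ring)
    return AnnotationSet(slide_id=sid, polygons=polygons)
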