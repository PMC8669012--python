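"""End-to-end orchestration: tile -> normalize -> split -> train -> predict ->
post-process (threshold | kernel) x gate (WSI | TMA) x aggregate (majority |
maxpool) -> evaluate.

Every intermediate is written under the output directory; a run log records
the config hash and seeds so reruns are reproducible.  The strategy matrix is
an explicit cross-product, so one run emits the full 2x2x2 report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as htio
from .classifier import (
    TilePrediction,
    predict_tiles,
    prepare_tiles,
    split_slides,
    train_classifier,
)
from .color_norm import ChannelStats, compute_channel_stats, reinhard_normalize
from .config import PipelineConfig
from .evaluation import accuracy_report, render_heatmap, roc_auc
from .postprocess import (
    ThresholdPair,
    apply_filter_kernel,
    apply_thresholds,
    call_majority,
    call_maxpool,
    fit_filter_kernel,
    grid_search_thresholds,
)
from .synthetic import CohortManifest, tissue_mask_of
from .tiling import SlideImage, build_tile_grid, filter_tiles
from .virtual_tma import select_tma_tiles, tma_regions

log = logging.getLogger("histotile")

MODES = ("threshold", "kernel")
GATES = ("WSI", "TMA")
AGGREGATES = ("majority", "maxpool")


@dataclass
class PipelineResult:
    out_dir: Path
    split: dict[str, str]
    thresholds: ThresholdPair
    reports: pd.DataFrame
    calls: pd.DataFrame
    slide_truth: dict[str, str] = field(default_factory=dict)
    preds_by_slide: dict[str, list[TilePrediction]] = field(default_factory=dict)
    tma_addrs: dict[str, set[tuple[int, int]]] = field(default_factory=dict)


def _load_slide(rec: dict, mpp: float) -> SlideImage:
    pixels = htio.read_image(rec["path"])
    return SlideImage(rec["slide_id"], pixels, microns_per_pixel=mpp,
                      true_class=rec["class"])


def run_pipeline(
    config: PipelineConfig, manifest: CohortManifest, out_dir: str | Path
) -> PipelineResult:
    """Run every stage on a cohort and emit the full strategy report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sub in ("tiles", "preds", "reports", "heatmaps"):
        (out / sub).mkdir(exist_ok=True)

    slide_truth = {r["slide_id"]: r["class"] for r in manifest.records}
    split = split_slides(manifest, config.fractions, config.split_seed)
    htio.write_json(out / "split.json", split.assignment)

    # --- tile + normalize + featurize every slide -------------------------
    reference: ChannelStats | None = None
    ref_id = sorted(split.slides("train"))[0]
    per_slide: dict[str, dict] = {}
    ordered = sorted(manifest.records, key=lambda r: r["slide_id"])
    for rec in ([r for r in ordered if r["slide_id"] == ref_id]
                + [r for r in ordered if r["slide_id"] != ref_id]):
        sid = rec["slide_id"]
        slide = _load_slide(rec, config.microns_per_pixel)
        mask = tissue_mask_of(slide, config.white_level)
        stats = compute_channel_stats(slide.pixels, mask)
        if reference is None:
            reference = stats
            htio.write_json(out / "reference_stats.json", stats.to_dict())
        normalized = reinhard_normalize(slide.pixels, stats, reference)
        norm_slide = SlideImage(sid, normalized, config.microns_per_pixel,
                                rec["class"])
        grid = filter_tiles(
            build_tile_grid(norm_slide, config.tile_px),
            norm_slide, config.max_white, config.white_level,
        )
        htio.write_tile_table(out / "tiles" / f"{sid}.tsv", grid)
        x, addrs = prepare_tiles(norm_slide, grid)
        anns = htio.read_annotations(rec["annotation_path"], slide_id=sid)
        regions = tma_regions(anns, config.microns_per_pixel, config.tma_radius_um)
        tma_grid = select_tma_tiles(grid, regions)
        per_slide[sid] = {
            "grid": grid,
            "x": x,
            "addrs": addrs,
            "tma_addrs": {(t.row, t.col) for t in tma_grid.tiles},
            "class": rec["class"],
        }
        log.info("prepared %s: %d kept tiles, %d TMA tiles",
                 sid, len(addrs), len(tma_grid.tiles))

    # --- train ------------------------------------------------------------
    def stack(part: str):
        xs, ys = [], []
        for sid in split.slides(part):
            d = per_slide[sid]
            if d["x"].shape[0]:
                xs.append(d["x"])
                ys.extend([d["class"]] * d["x"].shape[0])
        return (np.concatenate(xs) if xs else np.zeros((0, 64, 64, 3))), ys

    x_train, y_train = stack("train")
    x_val, y_val = stack("val")
    model = train_classifier(x_train, y_train, config.to_train_config(),
                             x_val, y_val)
    htio.write_json(out / "history.json", model.history)

    # --- predict every slide ---------------------------------------------
    preds_by_slide: dict[str, list[TilePrediction]] = {}
    for sid, d in per_slide.items():
        preds_by_slide[sid] = predict_tiles(model, d["x"], d["addrs"])
        htio.write_predictions(out / "preds" / f"{sid}.tsv", preds_by_slide[sid])

    def pooled(part: str) -> list[TilePrediction]:
        return [p for sid in split.slides(part) for p in preds_by_slide[sid]]

    # --- fit post-processing parameters ----------------------------------
    thresholds = grid_search_thresholds(pooled("val"), slide_truth,
                                        config.grid_step)
    htio.write_json(out / "thresholds.json", thresholds.to_dict())
    kernel = fit_filter_kernel(pooled("train"), slide_truth)
    htio.write_json(out / "kernel.json", kernel.to_dict())

    # --- strategy matrix on the test split -------------------------------
    report_rows, call_rows = [], []
    test_slides = split.slides("test")
    for mode in MODES:
        for gate in GATES:
            tile_pred, tile_true = [], []
            calls_by_agg: dict[str, list] = {a: [] for a in AGGREGATES}
            for sid in test_slides:
                preds = preds_by_slide[sid]
                if gate == "TMA":
                    preds = [p for p in preds
                             if (p.row, p.col) in per_slide[sid]["tma_addrs"]]
                if not preds:  # fully gated-out slide: fall back to WSI tiles
                    preds = preds_by_slide[sid]
                if mode == "kernel":
                    preds = apply_filter_kernel(kernel, preds)
                    retained = preds
                else:
                    retained = apply_thresholds(preds, thresholds)
                eval_preds = retained if retained else preds
                tile_pred += [p.label for p in eval_preds]
                tile_true += [slide_truth[sid]] * len(eval_preds)
                calls_by_agg["majority"].append(call_majority(preds, retained))
                calls_by_agg["maxpool"].append(call_maxpool(preds, retained))
            tile_rep = accuracy_report(tile_pred, tile_true, level="tile")
            report_rows.append(_report_row("tile", mode, gate, "-", thresholds,
                                           tile_rep, auc=None))
            for agg in AGGREGATES:
                calls = calls_by_agg[agg]
                rep = accuracy_report([c.call for c in calls],
                                      [slide_truth[c.slide_id] for c in calls],
                                      level="slide")
                roc = None
                truths = {slide_truth[c.slide_id] for c in calls}
                if len(truths) == 2:
                    roc = roc_auc([c.score for c in calls],
                                  [slide_truth[c.slide_id] for c in calls])
                report_rows.append(_report_row("slide", mode, gate, agg,
                                               thresholds, rep,
                                               auc=roc.auc if roc else None))
                for c in calls:
                    call_rows.append({
                        "slide_id": c.slide_id, "mode": mode, "gate": gate,
                        "method": c.method, "call": c.call,
                        "score": c.score, "n_retained": c.n_retained,
                        "fallback_used": int(c.fallback_used),
                    })

    # --- heatmaps for the test slides ------------------------------------
    for sid in test_slides:
        grid = per_slide[sid]["grid"]
        render_heatmap(preds_by_slide[sid], grid.n_rows, grid.n_cols,
                       out_path=out / "heatmaps" / f"{sid}.png")

    reports = pd.DataFrame(report_rows)
    calls = pd.DataFrame(call_rows)
    reports.to_csv(out / "reports" / "strategy_report.tsv", sep="\t", index=False)
    calls.to_csv(out / "reports" / "slide_calls.tsv", sep="\t", index=False)
    htio.write_json(out / "run_log.json", {
        "config_hash": config.config_hash(),
        "config": config.model_dump(mode="json"),
        "seeds": {"split": config.split_seed, "train": config.train_seed},
        "n_slides": len(manifest.records),
    })
    return PipelineResult(out, split.assignment, thresholds, reports, calls,
                          slide_truth, preds_by_slide,
                          {sid: d["tma_addrs"] for sid, d in per_slide.items()})


def _report_row(level, mode, gate, aggregate, thresholds, rep, auc):
    return {
        "level": level,
        "strategy": mode,
        "thresholds": (f"NS={thresholds.t_ns:.2f},S={thresholds.t_s:.2f}"
                       if mode == "threshold" else "-"),
        "gate": gate,
        "aggregate": aggregate,
        "overall": rep.overall_accuracy,
        "acc_NS": rep.per_class_accuracy.get("NS", float("nan")),
        "acc_S": rep.per_class_accuracy.get("S", float("nan")),
        "n_NS": rep.n.get("NS", 0),
        "n_S": rep.n.get("S", 0),
        "auc": auc if auc is not None else float("nan"),
    }
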