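# histotile

Tile-based whole-slide-image (WSI) classification pipeline for a two-class
tumour subtyping task (squamous `S` vs non-squamous `NS`), exercised
end-to-end on seeded synthetic histology-like slides:

1. **synthetic** — virtual-biopsy generator: tissue fragments on a white
   background, class-specific tumour textures, stroma, per-slide stain
   shifts, GeoJSON tumour annotations, TSV manifest.
2. **tiling** — non-overlapping 220×220 px grid; tiles with more than 2/3
   white background (all channels ≥ 0.94) removed.
3. **color_norm** — Reinhard normalization (Lab mean/sd matching against a
   reference slide) and `[0, 1]` scaling.
4. **classifier** — slide-grouped 60/20/20 split, flip/rot90 augmentation,
   weighted cross-entropy (×1.5 on misclassified examples), Adam
   (momentum 0.9, ε = 1e-7, lr 0.001 decayed ×0.9 every 5 epochs, batch
   100). Default backbone is a small NumPy CNN that trains on CPU.
5. **postprocess** — per-class confidence thresholds by exhaustive grid
   search over {0.5, …, 0.95}²; spatial "filter kernel" re-estimation via
   logistic regression over 8-neighbourhood label features; slide calls by
   majority vote or max pooling.
6. **virtual_tma** — 500 µm-radius cores around annotation centroids;
   restricts tiles to tumour regions.
7. **evaluation** — overall/per-class accuracy reports, ROC/AUC
   (Mann-Whitney), per-tile heatmaps (red = S, green = NS, grey = removed).
8. **pipeline / cli** — orchestration emitting the full
   (threshold|kernel) × (WSI|TMA) × (majority|maxpool) strategy report.

## CLI

```sh
histotile simulate --n-per-class 20 --out cohort/ --seed 1
histotile tile     --manifest cohort/manifest.tsv --out tiles/
histotile run      --manifest cohort/manifest.tsv --out run/ \
                   --epochs 10 --split-seed 0 --train-seed 0
```

`histotile run` writes every intermediate (tile tables, reference stats,
split, per-slide predictions, thresholds, kernel coefficients, heatmaps) plus
`reports/strategy_report.tsv` with tile- and slide-level accuracy/AUC for all
eight strategy combinations.

## Notes

- Everything is deterministic under the seeds exposed per stage.
- Synthetic textures are chosen for learnability by the small CNN, not for
  biological realism; parameters are centralized in
  `histotile.synthetic.TEXTURE_PARAMS`.
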