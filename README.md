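# hcscreen

Analysis toolkit for high-content phenotypic screens built on a per-cell
**cargo ratio** readout: the mean cargo fluorescence inside the trans-Golgi
network (TGN) divided by the mean over the remaining cell body. The package
covers the full loop from synthetic multichannel plates through hit triage:

- **`synthgen`** — synthetic data: calibrated genotype presets, deterministic
  plate layouts (96/384-well, edge-column controls, 11-point halving dose
  ladders), a tabular fast path for cascade-scale screens, and rendered
  4-channel fields (nucleus / cell body / TGN / cargo) with full ground truth.
- **`imaging`** — watershed segmentation (nuclei → nucleus-seeded cell bodies
  → per-cell TGN masks), per-cell cargo ratios, TGN shape descriptors
  (elongation, compactness, roughness) and an 85-feature profile vector.
- **`features`** — the versioned 85-feature manifest (nucleus, cytoskeleton,
  cell morphology, TGN, cargo/vesicles).
- **`screenqc`** — robust Z′, SSMD, inter-assay CV, plate gating,
  random-split replicate correlation, Mann–Whitney control separation
  (exact for small n) and train/test logistic AUC.
- **`hitcall`** — z-scores against same-plate negative controls, the
  activity (≤ −3 SD) / toxicity (≤ −2 SD) classification, and triage-cascade
  reports with half-up one-decimal percentages.
- **`doseresp`** — four-parameter logistic fits over log dose, EC50
  summaries, the dual-replicate multi-dose secondary activity criterion, and
  background-based artifact flagging.
- **`profiling`** — standardized feature matrices, SVD PCA, PC–feature
  correlations with driver selection (r > 0.75), per-condition profiles.
- **`pipeline` / `cli`** — end-to-end runs with config hashes, manifests and
  bit-identical reruns under fixed seeds.

## CLI

```sh
hcscreen simulate --out runs/demo --compounds 1000 --seed 0
hcscreen qc    --wells runs/demo/wells.csv --out runs/demo/qc.csv
hcscreen hits  --wells runs/demo/wells.csv --out runs/demo/calls.csv
hcscreen dose  --series series.csv --out fits.csv
hcscreen profile --cells cells.csv --out prof
hcscreen run-all --config config.yaml --seed 0
hcscreen analyze --fields fields_dir/ --out wells.csv   # TIFF fields
```

`simulate`/`run-all` accept `--mode images` to render and re-analyze actual
fields instead of using the tabular fast path. Fields are stored as
multi-page TIFF (channel order: nucleus, cell body, TGN, cargo) with a JSON
sidecar; all tables are plain CSV.

## Notes on the synthetic calibration

Published per-well control SDs pool within-plate and between-plate
variability. Presets therefore decompose each pooled SD into
`well_sd = pooled/3` and `plate_sd = pooled·√(1 − 1/9)`: pooled statistics
match the printed values while individual plates still clear the
robust Z′ ≥ 0.3 / SSMD ≥ 3 / CV ≤ 10% gates. Using the pooled SDs directly
as within-plate SDs makes robust Z′ collapse below 0.3 (demonstrated in the
acceptance suite).
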