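# avolipid

Untargeted LC-MS lipidomics pipeline and targeted acetogenin
quantification for avocado mesocarp, idioblast-enriched fractions and
seed, driven end-to-end by a ground-truth synthetic acquisition simulator.

The package covers:

- **`avolipid.synthetic`** — synthetic lipidomes and acquisitions: a local
  lipid reference database (TSV fixture, hierarchical category/main
  class/subclass codes), per-tissue/stage acetogenin profiles with stage
  trends (seed power-law accumulation, idioblast/mesocarp pairing, TAG
  decline and DAG remodeling), positive-mode ESI-TOF style centroided scan
  maps (m/z 150–1500, 0.94 scans/s, 65-min gradient) with adduct and
  isotopologue structure, drifting background channels, noise and dropout,
  plus 220-nm UV peak-area tables. Every injected peak is recorded in a
  ground-truth ledger for oracle comparisons.
- **`avolipid.signal`** — windowed-quantile 2D baseline correction
  (0.01 Da x 1.5 min cells, 40% quantile), grid-based chromatographic peak
  detection (min height 1000 counts, m/z tolerance 0.05, duration
  0.1–2.5 min, 0.1 min smoothing, 0.5 intensity-similarity ratio),
  isotopologue grouping (0.001 Da / 10 ppm, 0.25 min RT tolerance,
  monotonic envelopes, charge <= 2), RANSAC retention-time alignment
  (0.025 Da / 50 ppm, 2 min before / 1.5 min after correction, 25%
  inliers below 1 min) and predicted-window gap filling.
- **`avolipid.grouping`** — per-molecule grouping of co-eluting features:
  FWQM interval-overlap candidates confirmed by per-scan intensity
  correlation strictly above 0.9, single-linkage closure, and a
  deterministic adduct/fragment role annotator (Na-H, K-H, NH4-H
  differences; acetoxy-loss fragments at 60.0211 Da).
- **`avolipid.annotation`** — adduct hypothesis enumeration (4 singly, 16
  doubly charged), database search within 3 sd + 25 ppm, isotope-pattern
  verification with the sd/r^2 + 5% window, hierarchical 'fixed' vs
  'approximate' class-composition weighting, and putative-acetogenin
  signature flagging (O >= 4, odd carbon count, acetoxy loss).
- **`avolipid.quant`** — calibration-curve quantification of the
  acetogenin analytes (UPA in Persenone A equivalents; the co-eluting
  Persin/Persenone B peak on the Persenone B curve), TAC, profile shares,
  FW/DW basis conversion and fatty-acid summary tables with fold ratios.
- **`avolipid.stats`** — quantile normalization (tie-aware), log
  transform, feature-wise center/scale, SVD PCA, divergent-group selection
  on loadings, LOWESS/stage-mean trend curves, one-way ANOVA + Tukey HSD
  compact letters + Welch t-tests, signed fifth-power correlation heatmaps
  with average-linkage ordering, and the seed power-law TAC model with
  PC-score prediction.
- **`avolipid.io` / `avolipid.config` / `avolipid.pipeline` /
  `avolipid.cli`** — mzML (minimal self-contained subset) and long-format
  CSV scan maps, TSV reference DB, CSV tables throughout, a YAML-backed
  config whose defaults are the published method parameters, and a
  deterministic end-to-end pipeline with a checksummed manifest.

## CLI

```bash
# generate a synthetic cohort (scan maps, ledgers, profiles, UV areas)
avolipid simulate --tissue seed --stage 60 --stage 300 --replicates 3 \
    --seed 1 --out out/sim

# raw maps -> aligned, gap-filled feature table
avolipid process --maps-dir out/sim --seed 1 --out out/proc

# per-sample molecule grouping / annotation
avolipid group --maps-dir out/sim --seed 1 --out out/groups
avolipid annotate --maps-dir out/sim --db out/sim/lipid_db.tsv --seed 1 --out out/anno

# targeted quantification of a UV peak-area table
avolipid quantify --uv-table out/sim/uv_areas.csv --dw-fraction 0.3 \
    --seed 1 --out out/quant

# normalization + PCA + divergent-group selection
avolipid analyze --feature-table out/proc/feature_table.csv --seed 1 --out out/stats

# everything at once, with a manifest
avolipid run-all --seed 1 --out out/all
```

Any parameter can be overridden with `--config config.yaml`; see
`avolipid.config.PipelineConfig` for the full registry of defaults.

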