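# octinv

Quantification of cancer-cell invasion in 3D organotypic oral-cancer models
from OCT-like intensity volumes.

The package implements the full analysis chain as a tested, reusable
pipeline, driven by a synthetic phantom generator with exact programmed
ground truth (no raw volumes are publicly deposited for this assay, so the
phantom stands in for them):

- **`octinv.phantom`** — label volumes of organotypic models (top cancer
  slab, cohesive / finger / island invasion, spindle fibroblasts in the
  stroma) rendered into 16-bit OCT-like volumes with depth attenuation,
  mean-one Gamma speckle, anisotropic PSF blur and read noise. Truth values
  (baseline plane, ICCR volume, depth of invasion, per-island volumes) are
  computed by voxel enumeration at build time.
- **`octinv.volume_io`** — multi-page TIFF stacks (16-bit intensity, 8-bit
  labels + JSON sidecar), metric CSV tables; strict shape/range contracts,
  lossless round trips.
- **`octinv.segmentation`** — a trainable voxel classifier (multinomial
  logistic regression over multi-scale log-intensity, texture and
  normalized-depth features, fitted on labeled X–Z slices) standing in for a
  CNN behind a pluggable interface, plus an Otsu threshold baseline, ROI
  cropping and small-object cleanup.
- **`octinv.partition`** — baseline-plane estimation (robust mode of
  per-column contiguous-from-top run bottoms), split of the cancer mask into
  the original region and the invasive cancer-cell region (ICCR) with exact
  volume conservation, per-voxel connectivity to the original mass, and a
  26-connected 3D object counter.
- **`octinv.metrics`** — total / original / ICCR volumes, the hypothetical
  invasion front (HIF) as a lower-envelope height field and its triangulated
  surface area (a flat 500 × 500 µm front gives exactly 250,000 µm²), the
  mass invasion index (invasive fraction by default; the complementary
  printed form behind a flag), 3D depth of invasion, and per-field 2D
  section metrics (invasion index, depth of invasion).
- **`octinv.stats_report`** — Welch's t-test for cell-line and stroma
  factors, Mann–Whitney U (exact for small tie-free samples) for the day
  factor, two-sided at α = 0.05, and `run_pipeline` orchestrating
  phantom → segment → partition → quantify → compare from a YAML config.

## CLI

One entry point, `octinv`, with one subcommand per stage:

```sh
octinv phantom generate --spec spec.yaml --seed 3 --out ph/
octinv segment train --volume ph/volume.tif --labels ph/labels.tif --out model.json
octinv segment run --volume ph/volume.tif --model model.json --out seg.tif
octinv partition --labels seg.tif --out part.tif --report components.csv
octinv quantify --partition part.tif --out metrics.csv [--mass-index-form printed]
octinv compare --metrics metrics.csv --metric v_iccr_um3 --out comparisons.csv
octinv pipeline run --config study.yaml --out results/
```

`study.yaml` names a base phantom spec, a 2×2×2 design (cell_line × stroma ×
day) with replicate counts and per-condition phantom overrides, and the
metrics to compare; the run is deterministic given the config (every
replicate gets a derived seed).

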