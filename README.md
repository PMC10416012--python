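# stainpipe

A toolkit for hematoxylin-and-eosin (H&E) histology image analysis built
around a five-step slide-classification pipeline:

1. **Tiling** — magnification rescaling (local-mean), Otsu tissue
   segmentation, sliding-window tile extraction with a 10% minimum tissue
   fraction (224 px tiles at x10; stride 112 at inference, oversized
   316 px tiles at stride 56 for training).
2. **Geometric augmentation** — random rotation of the oversized tile with
   centre crop to 224 px, plus random horizontal reflection.
3. **Stain processing** — Beer–Lambert optical-density transforms,
   per-tile stain-matrix estimation (angular-percentile method on the
   top-2 principal plane of the OD cloud), stain **normalization** to a
   fixed target matrix, and stain **jittering** (element-wise
   U(0.75, 1.25) perturbation of the estimated matrix).
4. **Tile classification** — a pluggable classifier contract
   (binary cross-entropy / Adam; desk-scale MLP backend by default) that
   scores each tile in [0, 1].
5. **Slide aggregation** — positive-tile fraction per slide, an
   accuracy-maximizing decision threshold γ, confusion metrics
   (accuracy / sensitivity / specificity / precision / F1), ROC + AUC,
   and bootstrap confidence intervals.

A synthetic slide generator with planted ground truth (stain matrices,
tissue masks, class-dependent texture, "virtual scanner" profiles with
background tints and noise) makes the whole pipeline runnable and testable
without any external data, including cross-scanner domain-shift
experiments in three arms: **NP** (no processing), **SN** (stain
normalization applied to training *and* validation tiles), and **SJ**
(stain jittering applied to training tiles only).

## Quick start (library)

```python
import numpy as np
from stainpipe import (
    DEFAULT_TARGET_MATRIX, SlideParams, TileSpec,
    normalize_stains, jitter_stains, segment_tissue, extract_tiles,
    generate_slide,
)
from stainpipe.synthetic import default_profile

slide = generate_slide(SlideParams(height=1024, width=1024,
                                   label="positive", seed=0),
                       default_profile())
mask = segment_tissue(slide.image)
tiles = extract_tiles(slide.image, mask, TileSpec(), mode="inference")
normed = normalize_stains(tiles[0].pixels, DEFAULT_TARGET_MATRIX)
```

## Quick start (CLI)

```bash
# synthetic dataset of 5 positive + 5 negative slides
stainpipe simulate --out-dir data/train --n-pos 5 --n-neg 5 --seed 1

# rescans of the same virtual biopsies on a shifted scanner
stainpipe simulate --out-dir data/val-shift --n-pos 5 --n-neg 5 --seed 2 \
    --shift-rotation 18 --shift-background -20 -12 -4

# one arm end to end (report JSON + ROC CSVs in out/)
stainpipe train --arm SN --train-manifest data/train/manifest.csv \
    --val-manifest shifted=data/val-shift/manifest.csv \
    --out-dir out --seed 1

# all three arms
stainpipe experiment --train-manifest data/train/manifest.csv \
    --val-manifest shifted=data/val-shift/manifest.csv --out-dir out

# QA grid of example tiles
stainpipe qa-grid --manifest data/train/manifest.csv --out grid.jpg
```

Other subcommands: `tile` (tile manifests), `normalize` / `jitter`
(single-tile stain ops), `evaluate` (pretty-print a report).

## Tests

```bash
python -m pytest -q
```

`tests/test_acceptance.py` contains the acceptance criteria, including a
scaled-down cross-scanner replication (three seeds, NP vs SN arms) that
takes a couple of minutes on one CPU.

## Notes

- The packaged default target stain matrix (`DEFAULT_TARGET_MATRIX`) is
  the classic H&E absorption-direction pair, unit-normalized; pass your
  own 3x2 matrix (JSON) to reproduce a specific staining reference.
- Validation-tile processing follows the arm: normalized only in SN,
  never jittered. The decision threshold γ is re-selected per validation
  set (accuracy-maximizing), which is an optimistic protocol — keep the
  validation sets honest.
- Bootstrap intervals are percentile intervals over slide-level
  resampling; classifier backends other than the built-in MLP can be
  registered by extending `stainpipe.classify`.
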