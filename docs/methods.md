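# Methods

## Problem setting

Structure depictions in patents and journal articles are line drawings on a
(mostly) white page, interleaved with text, tables and other figures. The
segmentation task is pixel-first: predict which pixels belong to structures,
refine that prediction against the page's actual ink, and emit one crop per
contiguous structure entity. `chemseg` implements the three stages —
synthetic supervision, neural mask prediction, deterministic refinement —
plus a false-positive filter and an evaluation harness.

## Synthetic page generator

The generator is the package's definition of the study conditions, not a
tuning knob. Fixed conditions: single-molecule pages place 1–6 drug-like
molecules with 15–28 heavy atoms; cluster pages place one multi-fragment
record with 250–300 total atoms (hydrogens included), its fragments rendered
individually and shelf-packed with an 8 px gap to mimic fragment coordinates
drawn in close proximity; every depiction is rotated uniformly within 0–30°;
bond-line thickness varies over 1–3 px; pages are 512×512; placed assets
never overlap.

Choices the source conditions leave open, fixed once here:

- **Binarization-exact compositing.** Depiction ink (any rendered pixel
  below intensity 250) is composited clamped to intensity ≤ 200 on a pure
  white page. Consequence: the ground-truth mask coincides exactly with the
  pipeline's mean-threshold binarization of the page, so exact-recovery
  properties are well defined. This models crisp born-digital documents, not
  noisy scans; tests passing here say nothing about JPEG artifacts, bleed-
  through or skew.
- **Rendering scale.** Single molecules render on a canvas of
  `170 + 3·heavy_atoms` px, cluster fragments on `110 + 2·heavy_atoms` px,
  and any depiction below 520 ink px is re-rendered thicker/larger. This
  keeps every structure comfortably above the 400 px viability threshold the
  refinement stage enforces, as in the source setting's full-page renders.
- **Placement geometry.** Overlap is tested on axis-aligned bounding boxes
  expanded by a 10 px margin (conservative), molecules additionally require
  an all-white base-page area with 9 px of grid headroom. Grid lines are
  1–2 px black rectangles at 6 px padding around a structure's tight ink
  bbox (probability 0.3/molecule); the 6 px gap exceeds twice the dilation
  radius, so grids never merge into structure entities.
- **Decoration.** Negative figures are synthesized bar charts, scatters and
  filled bands; paragraph-like text is drawn as rows of short dark runs.
  Both are placed as assets (so the no-overlap guarantee covers them) and
  never enter the mask. A user-supplied directory of molecule-free base
  pages is accepted in place of the white page.
- Rotation uses nearest-neighbour resampling for the ink mask (stays
  binary) and bilinear for the bitmap; ink counts are preserved within
  ±10%.

Determinism: `(config, seed)` fully determines output bytes; each page
derives a child seed from the top-level stream.

## Mask predictor

A promptable ViT segmenter in pure NumPy over a small reverse-mode autodiff
tape (`chemseg.autodiff`). The encoder is a standard pre-norm ViT (patch
embedding as a strided linear map, learned positional embeddings, multi-head
attention, GELU MLP) with two residual bottleneck adapters per block —
after attention and before the MLP — and a two-layer 1×1-conv neck, each
conv followed by layer normalization (the "regularization" reading adopted
here). Adapters are `x + up(ReLU(down(x)))` with zero-initialized
up-projections, so a freshly built model reproduces its backbone exactly;
this identity is a tested invariant.

The decoder sums dense prompt and image embeddings, upsamples 4× via two
stride-2 transposed convolutions (implemented exactly as per-pixel linear
maps plus pixel shuffle), and classifies each pixel with
`logits = u · (w_static + w_dyn)`, where `w_dyn` comes from an MLP on the
pooled embedding (the dynamic linear classifier) and starts at zero. A
second MLP head predicts a scalar IoU estimate through a sigmoid. Points
and boxes are encoded with a fixed random Fourier basis plus learned type
embeddings; with no prompts a learned no-mask embedding is broadcast.
Free-text prompts are unsupported by design.

**Training.** Only adapters, prompt embeddings and decoder receive
gradients; backbone parameters carry none by construction and their SHA-256
hash is checked before/after. Defaults follow the reference conditions:
SGD, learning rate 0.001, momentum 0.9, batch 4, pixelwise binary
cross-entropy on sigmoid outputs, plus a small (0.1-weighted) MSE tying the
IoU head to the realized IoU.

Desk-scale choices (the backbone here is randomly initialized, not
pretrained, and test budgets are minutes, not GPU-weeks):

- **Footprint targets.** Masks are supervised at the decoder's output
  resolution as structure *footprints*: a cell is foreground when its page
  area contains more than 2% structure ink (3×3 closing applied).
  Downscaling thin strokes 16× and thresholding would otherwise erase the
  target. Localization is the network's job; exact pixel assignment belongs
  to refinement — mirroring the coarse-mask-then-refine architecture of the
  overall system.
- **Input normalization** stretches per-sample "inkness" to [0, 1]; after
  16× downscaling, strokes differ from white by only a few percent
  otherwise.
- **Class weighting** (positive weight 2), **gradient-norm clipping** at 5,
  **lowest-loss parameter selection** over the run, and a **ridge-regression
  (LSUV-style) data-dependent init** of the static classifier vector from
  one frozen forward pass. With these, a tiny config (64 px input, patch 8,
  2 blocks, 48-dim embeddings, 32-dim neck, decoder widths 32/16) reaches
  mean training IoU 0.53–0.71 across training seeds when overfitting ten
  pages for 200 steps at learning rate 0.05, full batch. The paper-scale
  defaults (lr 0.001, batch 4) are kept as `TrainConfig` defaults but
  cannot move a random-feature model off the base rate in 200 steps.
- Training IoU compares thresholded (0.5) footprint predictions with
  footprint targets.

Inference (`predict_page_mask`) resizes any page to the model's square
input, runs the no-prompt path and resizes the probability map back.

## Mask refinement

All operations act on {0,1} arrays, 0-based row-major, half-open boxes.
Pipeline order: binarize page at its mean → Hough line removal on ink →
threshold probability map (≥ 0.5) → line removal on the mask → dilate mask
→ dilate ink → keep dilated-ink components touched by the mask → intersect
with raw ink → drop entities under the area-scaled threshold.

Numerical/design choices:

- Ink dilation (not only mask dilation) is what bridges the gap between
  detached atom-symbol glyphs and their bonds; entity grouping uses the
  dilated-ink component labels so one structure with detached labels stays
  one region, while the emitted mask keeps only true ink pixels.
- Connectivity 8 by default (bond strokes are frequently diagonal);
  configurable to 4.
- Dilation kernel: square of side `max(3, round(0.01 · max(H, W)))` — 5 px
  at 512.
- Small-entity threshold: 400 px at 512×512, scaled by area ratio
  (`round(400 · H·W / 512²)`); entities exactly at threshold are kept.
- Hough: probabilistic transform restricted to ±2° around 0°/90°, minimum
  segment length 0.5× the page dimension, 3 px gap, cleared in a 3 px band;
  a fixed RNG seed makes detection deterministic.
- The deletion rule is "no ink support": mask pixels outside every
  seed-touched ink component are discarded; dilation halo around true ink
  is likewise trimmed by the final intersection with raw ink.
- `update_mask` and the size filter are idempotent; dilation is monotone
  (superset), line removal and filtering never add pixels. These are tested
  as properties, and `update_mask` is checked exactly against a brute-force
  component-labeling oracle.
- A constant page binarizes to an empty ink map (documented, not an error).

## False-positive filter

The shipped verdict is a closed-form heuristic:
`score = exp(−(ln(d/0.07))²/2) · min(1, 4/aspect)` with `d` the crop's ink
fraction. The density band (center 0.07, log-σ 1.0) was measured once from
rendered structure crops (0.05–0.10) versus synthetic negatives
(0.29–0.60); ink-free crops score 0. The decision threshold is 0.5. Known
blind spot: sparse scatter plots can fall inside the structure density band.
The learned-filter route is a pluggable scorer with the same verdict
interface.

## Evaluation

Greedy one-to-one bounding-box matching by descending IoU at a 0.5
threshold (the match criterion left open by the source is fixed here).
completeness = matched truth / total truth; redundancy = unmatched
predictions / total predictions, reported as 0% with an explicit flag when
there are no predictions. The greedy matcher is tested against a
brute-force all-pairs oracle on small instances.

## Scope and limitations

- PDF/SVG ingestion needs a rasterizer backend that is not bundled; raster
  images (PNG/JPG/…) are supported, and PDFs should be rasterized upstream.
- The synthetic generator emulates layout, rotation, line thickness,
  clusters, grids and negatives, but not scan noise, color, touching
  structures, reaction schemes or Markush decorations; results on it bound
  what the pipeline can do on clean documents, not on degraded scans.
- The full-size (SAM-B-scale) encoder configuration builds and runs but is
  slow on CPU and ships without pretrained weights; the tiny configuration
  is the tested default.
- Problem sizes used by the shipped checks: 100 pages for generator
  invariants, 20 pages for round-trip evaluation, 10 pages / 200 steps for
  the training smoke test, 1,000 placements / 200 pages for the acceptance
  measurements.
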