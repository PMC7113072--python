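# Methods

## Overview

`histocompress` measures two things as a function of lossy image
compression: (i) the performance of a patch classifier trained on
uncompressed images and evaluated on compressed ones, and (ii) the
stability of nuclear-architecture summary statistics derived from the
classifier's segmentations. All experiments run on synthetic
histology-like scenes with exact ground truth, so results are fully
reproducible from a single integer seed and require no external cohorts.

## Synthetic scenes

The generator (`synth.py`) emulates H&E-stained tissue with a flat
two-color stain model: hematoxylin-like purple nuclei (RGB ≈ (90, 60, 140))
on an eosin-like pink background (≈ (230, 180, 200)), with per-object color
jitter, within-nucleus Gaussian chromatin texture, and additive background
noise. A physical stain-deconvolution model is deliberately avoided: the
codecs under study operate on RGB, and what matters for them is realistic
chroma structure, not stain chemistry.

Defaults describe carcinoma tissue at roughly 10x magnification
(~1 µm/px):

| parameter | default | meaning |
|---|---|---|
| `width`, `height` | 256 px | field of view |
| `cell_density` | 20 per 10⁴ px² | ≈ 2,500–3,000 nuclei/mm²; ~130 cells per field |
| `nucleus_radius_mean` / `sd` | 4 / 1 px | ~8 µm nuclei |
| `eccentricity_range` | (0, 0.7) | drawn uniformly per nucleus |
| `texture_sd` | 10 | chromatin texture (8-bit units) |
| `noise_sd` | 5 | background noise; scanner noise at 10x is low |
| `region_fraction` | 0.3 | tumor-region area fraction (region task) |
| `distractor_ratio` | 1.0 | distractor:target cells (lymphocyte task) |

Object count is Poisson with mean `cell_density·H·W/10⁴`. Placement is
uniform with rejection (≤ 50 retries) against centers closer than
0.8·(rᵢ+rⱼ), limiting but not forbidding overlap; overlaps resolve
later-id-wins so the label mask is always a partition, and ids are
compacted with centroids recomputed afterwards. The lymphocyte task renders
targets small, dark and near-circular against larger, paler, elliptical
distractors; the region task thresholds a low-frequency Gaussian random
field (biased by a radial bump to keep it connected) and bisects the
threshold until the largest component is within 10% of the requested area
fraction.

What the generator does *not* emulate: gland/tubule morphology, stromal
texture, staining gradients, scanner-specific artifacts, and
whole-slide-scale context. Passing results therefore demonstrate the
*pipeline's* behavior under compression — the rate-distortion geometry, the
cliff-shaped performance collapse, the relative fragility of feature
families — not absolute performance levels transferable to clinical
material.

## Compression

JPEG uses Pillow's baseline encoder (4:2:0 chroma subsampling below
quality 95, 4:4:4 at or above — this affects achieved PSNR and is therefore
fixed and documented). JPEG2000 uses OpenJPEG through Pillow: reversible
5/3 wavelets for lossless, irreversible 9/7 with rate targeting for lossy.

PSNR targeting bisects log₂(compression ratio) over [−10, 0] with
round-trip PSNR measurement at each step (≤ 30 iterations, tolerance
0.5 dB). Rate control is approximately log-linear in PSNR, which makes
bisection fast (typically < 10 iterations). Zero-MSE round trips report the
cap value 100 dB. Targets outside the image's reachable range — the
irreversible path saturates near ~55–60 dB on textured scenes, so e.g. a
90 dB target is unreachable lossily — raise a convergence error carrying
the closest encoding; the sweep records such levels best-effort and always
plots against *achieved*, not requested, PSNR.

Compression ratio is compressed bytes over raw bitmap bytes (H·W·3).
Studies whose originals are already-compressed scanner files divide by the
stored file size instead; absolute ratios differ between the two
conventions by the original files' own compression factor.

## Patch classifier

The classifier is a small multilayer perceptron (hidden layers 96 and 48)
over full-resolution 16×16 RGB patches (768 inputs scaled to [0,1]),
trained with Adam for 30 epochs at batch size 256. The 16 px patch gives
~2 nucleus diameters of context; full-resolution features let the model use
fine texture — the cue class that lossy compression destroys first. Patch
labels are the ground-truth class at the patch center; sampling is
balanced positive:negative per `TrainConfig.balance`; training doubles the
sample with one random dihedral transform (rotations {0, 90, 180, 270}
plus mirroring) per patch, which leaves class frequencies unchanged.

Training never sees a lossy-compressed image; the sweep writes a manifest
auditing this. One integer seed drives scene generation, patch sampling,
augmentation, and weight initialization, so a sweep is reproducible
end-to-end on a fixed machine (scikit-learn's MLP is deterministic given
`random_state` and a fixed thread count).

Dense inference scores patch centers on a stride-2 grid (reflection
padding at borders) and bilinearly upsamples the probability grid to full
resolution — a documented approximation to stride-1 scoring chosen for CPU
tractability. Binarization threshold and detection threshold default to
0.5; peak detection suppresses local maxima greedily so no two centers are
closer than `min_distance` (default: the nucleus radius).

## Metrics

Pixel F1 is 2TP/(2TP+FP+FN); two empty masks score 1.0 with a warning.
Pixel AUC is the Mann–Whitney statistic (ties credited 0.5), computed via
scikit-learn and cross-checked in the tests against exhaustive pair
counting. Detection matching maximizes matched pairs within the radius and,
among maximum matchings, minimizes total distance (Hungarian assignment
with a large infeasible cost); the tests verify it against brute-force
enumeration. Per-image metrics are averaged across test images (pooling
over pixels is available by concatenating masks but is not the default).

## Nuclear-architecture features

Exactly 77 first-order statistics in five families, computed from the
predicted segmentation (8-connected components of the binarized map,
`min_area` = 5 px², area centroids):

- **Voronoi (12)**: cell {area, perimeter, chord length} × {mean, SD,
  min/max, disorder}, cells clipped to the image rectangle;
- **Delaunay (8)**: per-triangle {side length, area} × the same four;
- **MST (4)**: Euclidean minimum-spanning-tree edge lengths (built on the
  Delaunay edge set; complete graph fallback for degenerate layouts) × four;
- **nuclear (27)**: per-object {area, eccentricity, compactness 4πA/P²} ×
  four (12), k-NN centroid distances for k ∈ {1,3,5,7} × {mean, SD,
  disorder} (12), plus density per 10⁴ px², object count, and occupied area
  fraction (3);
- **subgraph (26)**: clusters are connected components (≥ 3 nodes) of the
  centroid graph linked under `link_radius`; per-cluster {nodes, edges,
  average degree, hop diameter, convex-hull area, nearest inter-cluster
  distance} × four (24), plus cluster count and clustered-cell fraction (2).

SDs are population SDs; disorder is 1 − 1/(1 + σ/µ), a bounded transform
of the coefficient of variation. Statistics with vanishing denominators
(µ = 0 for disorder, max = 0 for min/max) or insufficient objects (e.g.
7-NN with < 8 nuclei, inter-cluster distance with < 2 clusters) are
recorded as missing, never as errors, so tables stay comparable across a
ladder even when heavy compression destroys the segmentation.

`link_radius` defaults to 5 × the nucleus radius. A smaller factor (2.5×)
was evaluated and rejected: connected-component bridging of the
stride-upsampled probability map merges nuclei closer than ~3 radii, so at
2.5× essentially no centroid pairs survive and the subgraph family is
empty; 5× measures clustering at the spatial scale the predicted centroid
process actually resolves (~10–16 clusters per default field).

**Stability.** For level *l* and feature *j*, the raw difference is
|f(l,j) − f(lossless,j)| averaged over test images (missing pairs are
excluded; an all-missing cell contributes 0). The relative difference
divides each feature column by its maximum over levels (0/0 → 0), so
every nonzero column peaks at exactly 1, the lossless row is identically
0, and the matrix lives in (0,1) as plotted in the heat map. Rows are keyed
by the nominal level (requested PSNR; lossless = 100) with achieved PSNRs
available in the metrics table. Feature changes need not be monotone in
compression and no monotonicity is asserted.

The exact membership of the 77-statistic ledger is this package's own
fixed convention (names and family partition are stable across runs and
versioned with the code); other implementations of the same feature
families may enumerate a different 77.

## Sweep protocol and problem sizes

`run_sweep` executes generate → split → train(clean) → per level:
compress, decode, infer, score → aggregate; for the nuclei task it
additionally extracts features per level and builds the stability matrix.
The default ladder is PSNR targets {18, 20, 22, 25, 30, 35, 40} plus
lossless — 18 dB is the practical floor of the lossy encoder, and higher
targets approach its saturation ceiling.

Default experiment sizes are deliberately desk-scale: 256×256 scenes, 10
training and 5 test scenes per sweep, 400 patches per scene, three
replicate seeds for headline numbers; the acceptance script trains on 60
scenes and tests on 20 per replicate (12 epochs there — the task converges
well before the 30-epoch default). A full sweep runs in well under a
minute on one CPU core; the acceptance computation in a few minutes.

## Known limitations

- The classifier is an MLP over raw patches, not a deep CNN; absolute F1
  values are not comparable to published CNN results on real tissue, and
  the package makes no such claim. The *relative* degradation under
  compression is the quantity of interest.
- The two-color stain model makes the task color-separable at baseline;
  real tissue offers weaker contrast, so real pipelines may degrade at
  milder compression than the synthetic cliff suggests.
- Bit-exact reproducibility across BLAS builds is not guaranteed for
  trained weights (floating-point reduction order); all other stages are
  integer/deterministic.
- JPEG evaluation uses one encoder (libjpeg via Pillow); other encoders'
  quality scales differ.
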