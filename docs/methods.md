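# Methods

## Scope and model

`phenoseg` implements a complete desk-scale phenotyping workflow for
seedling-stage row crops observed from a UAV: semantic segmentation of
plants against soil, canopy-coverage estimation from the predicted masks,
extraction of visible/red-edge/NIR vegetation indices and color statistics
over the plant-masked region, and multi-method selection of the features
that track coverage.

The segmentation task is binary (plant = 1, background = 0; stored masks
use the 0/255 PNG convention). Four encoder–decoder families are provided:

- **U-Net** — a symmetric encoder–decoder with skip connections; each
  encoder stage is two 3×3 conv + batch-norm + ReLU blocks followed by 2×2
  max-pooling, each decoder stage is nearest-neighbour upsampling, a 1×1
  channel projection, skip concatenation and a double-conv block.
- **SE-UNet** — identical to U-Net except that a squeeze-and-excitation
  (SE) channel gate is appended at the end of every encoder stage (after
  the second convolution, before pooling). The gate pools each channel to a
  scalar (squeeze), maps the descriptor through FC(C → ⌈C/r⌉) + ReLU +
  FC(⌈C/r⌉ → C) + sigmoid (excitation) and rescales the channels. The
  decoder carries no SE blocks. With the gates forced to 1 the network is
  exactly a U-Net, which the tests exploit as an equivalence oracle.
- **FCN** — an FCN-8s-style head: 1×1 score maps from the three deepest
  pyramid levels, fused by stepwise 2× upsampling and addition.
- **DeepLabv3+** — atrous spatial pyramid pooling (1×1, three dilated 3×3
  branches at rates 6/12/18, and a global image-pooling branch) on the
  deepest features, a 4× upsampled decoder fusing a projected low-level
  feature map, then full-resolution logits.

All four emit per-pixel 2-class logits at the input resolution and are
trained with unweighted pixelwise cross-entropy.

### The neural-network engine

The models run on a small CPU engine (`phenoseg.nn`) written on numpy:
im2col convolution (stride/padding/dilation), batch normalization, 2×2 max
pooling, nearest-neighbour upsampling, SE gates, softmax cross-entropy, and
SGD-with-momentum / decoupled AdamW optimizers. Every layer implements an
explicit backward pass; the test suite checks each against central finite
differences and checks AdamW's decoupling against the closed-form update on
a one-parameter quadratic. The engine is single-device and deterministic:
given one seed, batch order, augmentation draws and therefore entire loss
trajectories are bit-reproducible.

### SE placement and reduction ratio

The gate sits after the second convolution of each encoder stage, before
pooling — i.e. at the end of the stage, acting on the features that feed
both the skip connection and the next stage. The reduction ratio defaults
to r = 16, the canonical setting for SE designs; tests use r = 4 on narrow
desk-scale networks so the bottleneck keeps at least one unit
(⌈C/r⌉ ≥ 1 is enforced regardless).

### ResNet-101 backbone

`SegModelConfig(backbone="resnet101")` builds the standard [3, 4, 23, 3]
bottleneck layout behind the FCN and DeepLabv3+ heads. No pretrained
weights are shipped; the backbone is randomly initialised and exists to
make the full-scale configuration expressible. U-Net variants use the
builtin encoder only — a U-Net over a ResNet pyramid is a different
architecture and is deliberately not invented here.

## Training protocol

The reference protocol trains for 40 000 iterations with validation every
4 000, batch size 8, under one of two optimizer presets:

| preset | lr | momentum / betas | weight decay | LR floor |
|---|---|---|---|---|
| SGD | 0.0025 | 0.9 | 5e-4 (through the gradient) | 1e-4 |
| AdamW | 1e-4 | (0.9, 0.999) | 0.01 (decoupled) | 1e-6 |

The schedule is polynomial decay,
`lr(t) = (base − min)·(1 − t/T)^p + min` with p = 0.9 (the de-facto
semantic-segmentation default; the protocol names PolyLR without a power).
The floor values are treated as the exact LR at `t = T`. Model selection
uses validation macro IoU, the headline segmentation metric. Checkpoints
store the weights, batch-norm running statistics, optimizer moments, RNG
state and full history, so an interrupted run resumed from its checkpoint
retraces the uninterrupted run, with the schedule evaluated at the global
iteration counter.

Batch size (8) and the cross-entropy loss are package choices; the
reference protocol does not state them.

Desk-scale experiments (the test suite and `scripts/acceptance.py`) keep
every protocol element but shrink the problem: 300 iterations, validation
every 100, base width 16, 128×128 tiles, 240/24/24 train/val/test. These
sizes were chosen so a full run is a coffee-break on one CPU core while
still reaching ≥ 0.80 held-out macro IoU on the synthetic task.

## Augmentation

Three strategy families, each independently switchable:

- **scale** — resample by a factor from {0.5, 0.75, 1.25, 1.5, 1.75, 2.0}
  (bilinear for images, nearest-neighbour for masks, which provably keeps
  labels binary), then a seeded random crop; tiles smaller than the crop
  are padded reflectively first.
- **flip** — horizontal and vertical flips, each with probability 0.5,
  applied to image and mask together.
- **photometric** — brightness ±20 % of the value range and contrast
  ±15 % about the mid-point 127.5:
  `pixel' = clip(c·(pixel − 127.5) + 127.5 + d·255)`. An optional HSV
  saturation jitter (±15 %) exists but is disabled in the ablation preset,
  which isolates brightness/contrast only.

The ablation plan enables exactly one strategy per run and errors on any
other configuration.

## Inference

Long plot strips are predicted with a sliding window (default 512×512,
stride 256, desk-scale tests use the tile size): windows are placed at
stride offsets with the last window snapped to the border, softmax
probabilities are accumulated with a per-pixel count map and averaged, so
every pixel is covered at least once and overlaps blend smoothly.
Test-time augmentation averages probabilities over scales {0.75, 1.0,
1.25} × horizontal flip, after inverting each transform; scales that
would undershoot the network's minimum input are skipped with a warning.
Probability averaging (not majority vote) is used for both TTA and window
overlap because it is seam-free and preserves the per-pixel simplex.

## Metrics

Per class c treated as positive: IoU = TP/(TP+FP+FN), precision, recall,
F1 = 2PR/(P+R) (equal to Dice = 2TP/(2TP+FP+FN) on binary masks, an
identity the tests verify numerically along with F1 = 2·IoU/(1+IoU)), and
global accuracy. Macro values are unweighted means over the two classes.
Zero-denominator cases yield NaN sentinels excluded from macro averaging —
silently substituting 0 or 1 would bias averages on degenerate tiles. The
percent-table writer reports per-class recall in the per-class accuracy
column (the layout used by per-class segmentation tables, where the two
coincide) and labels global accuracy separately.

## Canopy coverage

Coverage = plant pixels / total pixels, an exact integer ratio, reported
as a fraction and as a percentage. Strips sharing a variety are pooled at
the pixel level (sum counts, then divide), which is well-defined for
unequal strip sizes and always lies between the per-strip extremes. The
coverage–trait operation is a plain Pearson correlation over
variety-matched pairs, with explicit errors for fewer than three pairs or
zero variance.

## Features

Band symbols denote the average reflectance over the plant mask; indices
are computed means-first (a per-pixel-then-average mode exists behind a
flag for sensitivity checks). The battery: B, G, RGRI = R/G,
NGRDI = GRVI = NDGI = (G−R)/(G+R), VARI = (G−R)/(G+R−B),
MGVRI = (G²−R²)/(G²+R²), ExG = 2G−R−B, ExR = 1.4R−G, ExGR = ExG−ExR,
COM = 0.25·ExG + 0.3·ExGR + 0.33·CIVE + 0.12·VEG, NDRE = (NIR−RE)/(NIR+RE),
GNDVI = (NIR−G)/(NIR+G), GRNDVI = (NIR−(G+R))/(NIR+(G+R)), plus mean HSV
hue H and saturation S and mean CIELab a* (D65) over the mask.

Notes on definitions:

- CIVE = 0.441R − 0.811G + 0.385B + 18.78745 and
  VEG = G/(R^0.667·B^0.333) are the canonical published forms; COM uses
  them as components.
- GRNDVI follows the standard green-red normalized difference definition
  given above.
- S (saturation) is provided as the HSV saturation mean.
- Width-index statistics (WI mean/sd) are not implemented: WI has no
  usable definition available to this package.
- Zero denominators produce NaN with a per-feature validity flag.

RGB-only inputs produce the visible-band subset and flag the NIR indices
as unavailable rather than fabricating values.

## Feature selection

Four routes against coverage as the response, all column-order invariant
and seeded:

- **Pearson screen** — all features with |r| > 0.8 (strict), sorted by |r|.
- **LASSO** — an L1 path over a 100-point geometric lambda grid from
  λ_max = max|X'y|/n, 5-fold CV, and the one-standard-error rule (the
  sparsest λ within one SE of the CV minimum). The 1-SE rule is the
  conservative choice consistent with producing a deliberately streamlined
  subset.
- **LARS** — the first k entries of the least-angle path; k defaults to
  the size of the Pearson screen. Exact collinear ties resolve
  first-by-column-name.
- **CARS** — N = 50 Monte-Carlo runs, each fitting PLS on an 80 % row
  sample; features are weighted by normalized |PLS coefficient|, the
  retention budget decays exponentially with r₁ = 1 and r_N = 2/p
  (a = (p/2)^(1/(N−1)), k = ln(p/2)/(N−1)), enforced as a top-by-weight
  cut followed by weight-proportional resampling within the budget (never
  collapsing below two features); the run whose retained set minimizes
  5-fold RMSECV wins. PLS component count (≤ 5) is chosen by inner CV.

The consensus report gives per-feature selection frequency, the pairwise
overlap matrix and the core set (intersection of all methods).

## Synthetic data generator

The generator is the package's study environment, not a fixture: every
downstream claim is validated against its exact ground truth.

- **Tiles** — plants are unions of three randomly perturbed ellipses
  (cheap, controllable, irregular canopy outlines), count ~
  Poisson(density); soil is a smoothed value-noise texture; a linear
  illumination ramp of amplitude 0.25 and darkened half-annulus shadows
  (probability 0.3 per plant, soil pixels only) provide the nuisance
  structure. Default palette: foliage RGB (52, 120, 58) ± 10, soil
  (138, 102, 72) ± 13 — a mean separation ≥ 3× the within-class spread, so
  a small network can learn the task in minutes. Masks are exact by
  construction and `true_coverage` is the literal pixel count ratio.
- **Strips** — plants are added one at a time against a live mask with
  radii capped by the remaining deficit, so realized coverage lands within
  ±0.02 of the target (typically within 1e-4).
- **Multispectral** — R, G, B from the rendered tile plus red-edge and NIR
  bands in which plant pixels are bright (NIR strictly above R by
  construction, soil NIR ≈ soil R), mimicking the red edge of healthy
  vegetation.
- **Feature tables** — k informative columns share a latent factor with
  equicorrelation 0.6 and the response is their weighted sum plus Gaussian
  noise (sd 0.1). The shared factor is essential, not cosmetic: for
  mutually independent predictors the squared correlations with a common
  response sum to at most one, so "every informative feature has
  |r| > 0.8" is achievable only with collinear informative features —
  exactly the situation of real vegetation indices, which are arithmetic
  combinations of the same few bands. Columns are standardized; noise
  columns are independent.

What the generator does **not** emulate: real leaf morphology and texture,
specular soil reflections, perspective and stitching artifacts, weeds,
inter-plant occlusion structure, or sensor noise statistics. Passing the
desk-scale learnability tests therefore demonstrates that the training
loop, architectures and evaluation chain work end to end — not that the
networks reach any particular accuracy on real UAV imagery.

The illumination-shift benchmark used by the ablation test trains on tiles
with low illumination variation (amplitude 0.05) and evaluates on tiles
given a global +20 % brightness / +15 % contrast shift. This constructed
nuisance makes the expected ordering checkable: the photometric-ablation
run, which alone saw brightness/contrast jitter during training, should
beat the scale-ablation run on the shifted test set.

## Numerical choices and degenerate inputs

- Images resample bilinearly; masks by explicit nearest-neighbour index
  maps (binary labels survive exactly; ×2 scaling reduces to pixel
  replication, which the tests check).
- Reflective padding wherever a tile is smaller than a crop or window;
  padded regions are cropped away from returned predictions.
- Normalization statistics are computed once from the training split and
  stored in checkpoints.
- Non-finite losses abort training with a diagnostic rather than
  continuing silently; NaN inputs to inference are rejected.
- Empty plant masks raise explicit empty-mask errors in feature
  extraction; zero-variance columns are excluded from the Pearson screen
  with a warning; degenerate responses are errors.
- LR schedule queries beyond the horizon clamp to the floor with a warning.

## Known limitations

- The CPU engine is deliberately small: no GPU path, no mixed precision,
  no operator fusion; 40 000-iteration base-64 training is expressible but
  not practical on one core.
- The FCN/DeepLabv3+ decoders use nearest-neighbour upsampling rather than
  learned transposed convolutions or bilinear interpolation; at desk scale
  this is indistinguishable, at full scale it slightly coarsens boundaries.
- The ResNet-101 backbone is untrained; comparisons involving it reflect
  architecture shape only.
- Selection quality claims are validated on planted synthetic tables; on
  real feature batteries the methods inherit their usual caveats
  (collinearity makes the chosen representative within a correlated block
  somewhat arbitrary).
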