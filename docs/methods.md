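# Methods

This note records the models, conventions and numerical choices behind
`usfusion`, in the order data flows through the pipeline.

## Synthetic paired-patch model

Real B-mode/CEUS pairs of HCC lesions are private clinical data, so the
pipeline is driven by a generative stand-in that reproduces the
*statistical contrasts* the method exploits, not ultrasound physics.

Each patch channel is a smoothed Gaussian random field: white noise is
convolved with a Gaussian kernel whose bandwidth is the class
`correlation_length` (pixels), then affinely mapped to the class mean
and standard deviation.  The CEUS field shares a correlated component
with the B-mode field (`cross_channel_rho`) and, for HCC only, is
shifted upward by `ceus_enhancement_offset`, emulating arterial-phase
hyper-enhancement.  HCC patches additionally mix in 2–4 dark disks
(radius ~ U(3, 8) px, intensity 60 gray levels below the HCC mean) with
probability `necrosis_fraction`, mimicking necrotic cores.  Outputs are
clipped and rounded to 8-bit.

A zero-mean per-patch brightness jitter (`patch_jitter_sd`, shared by
every pixel of a patch pair) emulates acquisition-to-acquisition gain
variability.  Without it every patch of a class has nearly the same
spatial mean, any classifier saturates, and comparisons between fusion
strategies are vacuous.  Whole-frame synthesis disables the jitter
because both tissue types in one frame share one acquisition.

Defaults (gray levels on [0, 255], lengths in pixels):

| parameter | HCC | PAR | rationale |
|---|---|---|---|
| `bmode_mean` | 135 | 125 | HCC slightly hyperechoic |
| `field_sd` | 26 | 18 | HCC more heterogeneous |
| `correlation_length` | 4 | 2 | HCC coarser-grained |
| `ceus_enhancement_offset` | +22 | 0 | arterial hyper-enhancement |
| `necrosis_fraction` | 0.5 | — | dark-core mixture |
| `cross_channel_rho` | 0.5 | 0.5 | shared tissue structure |
| `patch_jitter_sd` | 18 | 18 | gain variability |

The effect sizes were calibrated once so that a from-scratch tiny CNN
on a single modality reaches roughly 0.8–0.9 test accuracy (measured:
B-mode 0.88, CEUS 0.89, decision fusion 0.93, means over 5 seeds at 60
patches/class), leaving headroom for fusion gains.  What passing tests
show is therefore that the *pipeline* orders fusion strategies
correctly when the two channels carry complementary signal — not that
the generator reproduces clinical ultrasound; it has no speckle
statistics, attenuation, or contrast kinetics.

## Patch extraction

Polygon vertices use the VIA convention (x = column, y = row, origin
top-left); pixel (r, c) has its center at (x=c, y=r).  The polygon
center is the arithmetic vertex centroid rounded to the nearest pixel.
The 250×250 search region is clipped to the image when the centroid is
near an edge, and candidate 51×51 tiles are anchored at the region's
top-left corner with stride 51 (hence mutually disjoint).  A pixel
center exactly on the polygon boundary counts as inside (deterministic
tie rule, implemented with `shapely.covers`).  The intersection of a
tile with the polygon is the count of covered pixel centers:
2601 → HCC, 0 → PAR, anything else discarded to keep both classes pure.

Rotation augmentation produces the original plus 90/180/270-degree
rotations (both channels rotated identically; labels preserved).
Train-time augmentation applies random flips and integer translations
up to 5 px with half-sample symmetric border reflection, the same
convention `scipy.ndimage` uses elsewhere in the package.

## Texture features (41 per channel)

The fixed composition is: 6 Haralick statistics on the order-2
co-occurrence matrix + 6 on the order-3 matrix + 3 edge features +
autocorrelation + Hurst + 2 wavelet entropies + 22 Laws features.

* **GCMs.** Order 2 uses 256 gray levels and the eight unit
  displacements at 45° multiples; order 3 quantizes to 64 levels
  (sparse accumulation; a dense 256³ array would be prohibitive) and
  uses four collinear triples with the current pixel central plus four
  right angles with it at the vertex.  Haralick statistics (local
  homogeneity, energy, entropy, correlation, contrast, variance) are
  computed per displacement and arithmetically averaged; the
  45°-multiple family is closed under quarter turns, making the block
  rotation-invariant.  Order-3 generalizations: contrast and
  homogeneity use ((f1−f2)² + (f2−f3)²)/2, correlation is the mean of
  the three pairwise marginal correlations, variance averages the
  squared deviations of the three indices.  Degenerate marginals give
  correlation 0; an empty matrix is an error.
* **Edges.** 3×3 Sobel gradients; edge pixels exceed the mean gradient
  magnitude; features are the edge fraction, mean magnitude over edge
  pixels, and the circular variance of gradient orientation (0 when no
  edge pixels exist).
* **Laws.** Eleven retained 5×5 mask classes (E5E5, S5S5, R5R5, W5W5,
  L5E5, L5S5, L5R5, L5W5, E5S5, E5R5, E5W5 — all zero-sum, so constant
  patches respond 0; L5L5 and three high-order cross terms are dropped
  to reach the 41-feature total).  Asymmetric pairs are averaged into
  one energy map; density = fraction of pixels above the map mean,
  frequency = mean energy.
* **Hurst.** Slope of log mean absolute intensity increment vs log lag
  over lags 1..8 (horizontal + vertical pooled), clipped to [0, 1];
  zero-variance patches return 0.
* **Wavelet entropies.** Two orthonormal Haar levels (even-cropped,
  periodization mode, so energy is conserved exactly); per level the
  three detail subbands are pooled, squared, normalized to a
  distribution, and its Shannon entropy taken (0·log 0 = 0).
* **Autocorrelation.** Mean of the lag-(1,0) and lag-(0,1) normalized
  autocovariances; constant patches return 1 by convention.

No global intensity normalization is applied before feature
computation; only ratio-type features are illumination-invariant.

## Dimensionality reduction

Kernel PCA eigendecomposes the double-centered kernel matrix (the
centering is what makes the linear kernel reduce exactly to classical
PCA, which the tests assert to 1e−8).  Eigenvectors are scaled by
1/√λ so scores match PCA score scaling; out-of-sample projection
centers the kernel row consistently.  Kernels: linear, (x·y + 1)³, and
Gaussian with the median-pairwise-distance bandwidth heuristic.
Eigenproblems are always n×n in the number of training vectors.  At
classifier-level fusion the retained dimension defaults to 128 (capped
at n); PCA dimension matching for unequal branch vectors is fitted on
training features only.

## CNN branches

`usfusion.nn` is a small numpy layer framework (im2col convolutions on
BLAS, ReLU, 2×2 max pooling with a first-maximum tie rule, dense
layers, softmax cross-entropy, SGD with momentum).  All initialization
is He-scaled from an explicit seeded generator; training is
bitwise-reproducible on one platform with a fixed seed.

The trainable `tiny` branch (3 conv/pool blocks + 64-unit fully
connected tap + 2-way softmax, native input 51) is the workhorse for
simulation experiments.  The six large architectures (SqueezeNet,
GoogLeNet, the GoogLeNet-V1 variant with a residual shortcut replacing
its last three inception modules, ResNet-18, VGG-16, DenseNet-201) are
forward-only, randomly initialized shape-contract builds: their role in
this package is to expose the documented tap-layer dimensions
(392/394, 1024, 528, 512, 4096, 1920) and the activation-map export;
per-channel instance normalization keeps activations bounded through
deep untrained stacks.  Pretrained weights are deliberately out of
scope.  Grayscale patches are bilinearly resized to the native input
side, replicated to three channels where needed, and normalized by the
fixed affine map (x − 128)/64, which keeps the mid-gray working range
near unit scale without destroying absolute-brightness (enhancement)
information.

Training defaults follow the documented protocol (SGDM, learning rate
0.0002, momentum 0.1, minibatch 25, 70 epochs), which suits
*fine-tuning*.  A branch trained from random initialization cannot move
far enough in ~200 small steps, so desk-scale experiments use
`scratch_train_config()` (learning rate 2e−3, momentum 0.9, 40 epochs);
both are ordinary `TrainConfig` values.

## Fusion conventions

The CEUS argument always carries weight 2 in weighted means, at every
level.  Image-level multiplication uses the fixed rescaling
round(b·c/255): deterministic, monotone, exact at the endpoints, and
well-defined for constant images (a per-image min–max rescale would be
none of these).  Image-level outputs are rounded 8-bit; vector-level
fusion stays in floating point.  Decision-level fusion renormalizes
only to remove floating-point residue — means of valid probability
pairs are already valid.  SVM heads obtain probabilities through the
standard logistic (Platt-style) calibration of the margin.

## Feature selection

Continuous features are discretized by equal-frequency 10-bin binning
before any entropy computation (configurable).  CFS uses symmetric
uncertainty for both feature–class and feature–feature correlation and
Hall's merit; best-first search starts from the empty set, expands the
best open subset by one feature, and stops after 5 consecutive
expansions without improvement, with ties broken toward the
lexicographically smallest index tuple.  On every ≤10-feature dataset
tested the search matches exhaustive enumeration.  Gain ratio is
information gain over split information (0 when the split information
is 0), ranked descending with the 0.15 cutoff.  The union rule merges
selections ordered by original index.

## Evaluation

HCC is the positive class everywhere.  Splits are stratified per class;
an optional group id keeps augmented copies (or patients) on one side.
The decision threshold is 0.5 with ties assigned to HCC.  ROC curves
sweep the unique scores; AUC is trapezoidal and equals the normalized
Mann–Whitney statistic.  Undefined metric ratios (empty margins) return
0 rather than raising mid-experiment.

## Problem sizes and determinism

Simulation experiments in the tests use 60 patches/class, 5 seeds, and
the tiny branch — sizes chosen so the full behavioural suite completes
in minutes on one CPU core while the seed-averaged orderings
(decision fusion ≥ best single modality; combined-channel texture ≥
B-mode-only texture; label-shuffled runs at chance) are stable.  All
randomness flows from explicit integer seeds; cross-platform bitwise
identity is not promised, same-platform reproducibility is.

## Known limitations

* The generator omits speckle, attenuation, depth-dependent gain and
  contrast kinetics; results on it bound what the pipeline can show
  about real ultrasound.
* The large backbones are untrained shape contracts; their tap features
  are random projections, useful for interface and dimension tests, not
  for recognition performance.
* The texture-feature composition reaching exactly 41 elements is a
  documented package contract; other compositions are configurable but
  change the vector length.
* AdaBoost uses CART base trees rather than C4.5.
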