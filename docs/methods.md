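# Methods

This note documents the models, numerical choices and limitations of
`cariodet`, in the order of the pipeline.

## Geometry model

Volumes are 3D scalar grids with per-axis spacing in millimetres, in a fixed
(axial, coronal, sagittal) index order with 0-based indices and half-open
voxel ranges; for single-tooth volumes axis 0 is the tooth long axis.
Spacing and origin are quantized to float32 on construction — the precision
of the NIfTI-1 header — which makes geometry metadata survive NIfTI/NRRD
write/read round trips bit-exactly.  DICOM series are read-only (slices
sorted by position along the normal; an irregular slice pitch beyond 1% of
the median raises a geometry error); NIfTI is the interchange format.
Intensities are stored as float32 with no Hounsfield calibration, since CBCT
grey values are not HU.

Resampling uses `scipy.ndimage.zoom` with grid-aligned (pixel-area)
semantics: trilinear for intensities, nearest neighbour for masks (so masks
stay strictly binary).  Isotropic resampling computes output extents as
`round(extent * spacing / target)` per axis (minimum 1), preserving physical
extent to within one voxel per axis.  Fixed-shape resizing offers two modes:
`interpolate` (default; per-axis rescaling, spacing adjusted so physical
extent is preserved) and `pad_crop` (centred zero-padding/cropping, spacing
kept).  Both record enough information (`ScaleRecord`) to invert the shape
change exactly.

## Tooth extraction

A tooth sub-volume is produced by crop → isotropic resample → fixed-shape
resize, recorded in an invertible `CropTransform`.  Choices where the
procedure is genuinely open:

* **Margin conversion** — the physical margin (default 3 mm) converts to
  `round(margin / spacing)` voxels per axis, treating anisotropic sources
  symmetrically.
* **Border handling** — expanded boxes are clipped at the scan border, not
  padded; clipping avoids inventing intensities.
* **Disconnected masks** — the box covers the union of all components, since
  multi-rooted teeth may disconnect after resampling.
* **Restore path** — predictions are mapped back by inverting the resize,
  resampling to the box shape (nearest for boolean grids, trilinear
  otherwise) and embedding into a zero background, so restored predictions
  always have support inside the expanded box.

Defaults: margin 3 mm, target spacing 0.25 mm, input shape 96 × 64 × 64,
reached by interpolation (`pad_crop` available).  Tests and demos use
32³ inputs at 0.5 mm to keep CPU runtimes in seconds-to-minutes; the
geometry code is scale-free.

## Network

A fully convolutional attention 3D U-Net with deep supervision and a
tooth-level classification head, implemented in NumPy on a small
reverse-mode autodiff engine (`cariodet.autograd`) whose operators are
gradient-checked against central finite differences.  Architecture:

* encoder: one 3×3×3 convolution per level; levels connected by 3×3×3
  stride-2 convolutions; channels double per level from `base_channels`;
* decoder: nearest-neighbour ×2 up-sampling; skip features gated by an
  additive attention gate and concatenated; each block is a 3×3×3
  convolution (to 2·C) followed by a 1×1×1 convolution halving the feature
  maps (to C);
* attention gates: 1×1×1 stride-2 projection of the skip, 1×1×1 projection
  of the gate, add, leaky ReLU, 1×1×1 to one channel, sigmoid — one scalar
  coefficient per spatial location, broadcast over channels, upscaled to the
  skip resolution with nearest-neighbour interpolation (matching the
  network's up-sampling path; a per-voxel-per-channel variant was
  considered and rejected as inconsistent with a "single scalar" gate);
* deep supervision: a 1-channel 1×1×1 segmentation head per decoder level,
  upscaled (nearest) to full resolution, combined by element-wise summation
  before the final sigmoid;
* classification head: global average pooling of the deepest features, a
  dense layer, sigmoid;
* instance normalization after every convolution (batch statistics are
  meaningless at batch sizes of 1–2 volumes) and leaky ReLU (slope 0.01).

Weights are freshly initialized (He normal) from the config seed; nothing
is pre-trained.  Input spatial dimensions must be divisible by
2^(levels − 1).  Defaults (4 levels, 8 base channels) and the test-scale
configuration (3 levels, 4 channels, ~18k parameters) are both CPU-trainable;
everything is configurable.

**Loss.** Segmentation: (1 − soft-Jaccard) + voxel-mean binary cross
entropy, with ε = 10⁻⁶ smoothing so the empty/empty Jaccard is 1 by
convention and the loss is defined everywhere; probabilities are clipped at
10⁻⁷ in the cross-entropy.  Classification: binary cross-entropy, weighted
1:1 with the segmentation loss.  Optimization: Adam, default learning rate
1e-3, batch size 2, no schedule; the phantom experiments in the test suite
and acceptance script use 3e-3 for faster convergence at their small scale.
Runs are bit-reproducible given the weight seed and batch-order seed.
Volumes are z-score normalized per volume before the network.

The estimator interface (`CariesSegmenter`) wraps configuration, training
and prediction in scikit-learn conventions (`get_params`/`set_params`,
`fit(X, y)` on stacks of volumes and masks, fitted attributes `network_`,
`loss_history_`), so the segmenter composes with sklearn model selection.

## Post-processing

Order of operations: recalibrate and threshold voxel probabilities
(cutoff 0.5 on the recalibrated scale, i.e. the Youden operating point of
the raw output) → intersect with the dilated tooth mask → connected
components → physical-volume filter.  Restricting to the tooth *before*
labeling, rather than last, is deliberate: it is the only order under which
both stated output guarantees hold simultaneously — every surviving
component meets the volume threshold, and the operation is idempotent
(intersecting last can split or shrink a component below threshold after it
was filtered).

* **Connectivity** — 26 by default (6/18 available) for both labeling and
  the dilation structuring element; dilation radius default 1 voxel.
* **Volume filter** — strict-less removal: a component of exactly the
  threshold volume is retained.  The default threshold is 0.3 cm³
  (= 300 mm³).  This printed value is very large relative to a whole tooth
  (~1 cm³) and plausibly means 0.3 mm³; the package keeps the printed value
  as the default rather than silently "fixing" it, and exposes it in
  `PipelineConfig.min_lesion_volume_cm3` (the demo config uses 0.001 cm³).
* **Recalibration** — t* maximizes sensitivity + specificity over the
  midpoints of adjacent distinct predicted probabilities (ties broken toward
  the lower threshold); the map fixing {0, t*, 1} → {0, 0.5, 1} is the
  minimal monotone piecewise-linear function with the required anchor, and
  is strictly increasing and bijective on [0, 1] for every t* ∈ (0, 1).

## Phantoms

`PhantomSpec` describes a jaw segment: a row of teeth along axis 2, each a
superellipsoid crown (exponent 2.5, semi-axes default 3.2 × 2.2 × 2.2 mm)
fused with a tapered root (8 mm, 75% width, linear taper), dentin/enamel/
background grey levels in [0, 1] (enamel as a ~0.5 mm crown shell), and
additive Gaussian noise (default σ = 0.02, about 4% of dentin).  Approximal
lesions are spherical caps centred on the mesial (−axis 2) or distal
(+axis 2) crown surface point, intensity dentin·(1 − contrast) with
contrast 0.6; the cap radius is found by bisection until the realized voxel
volume is within 2% of the requested target (10% is a hard error).  Optional
streak artifacts add axis-aligned high-intensity lines (off by default,
qualitative only).  One seed per phantom, split into geometry/noise/streak
substreams, makes every product bit-reproducible.

Synthetic observers are two-stage: a latent binary call drawn with the
stated sensitivity/specificity against the surface truth, then a five-point
confidence score drawn from a distribution conditioned on (truth, call).
The default score distributions are binarization-consistent (positive calls
only yield scores 4–5), so the binarized ratings recover the stated
operating characteristics exactly in expectation.

What the phantoms do **not** emulate: projection/reconstruction physics,
scatter and beam hardening, real anatomical shape variation, restorations
and metal artifacts, lesion texture.  Passing tests therefore demonstrate
that the pipeline's geometry, optimization and statistics behave correctly —
not that the network reaches clinical accuracy on real CBCT, which would
require real annotated data.

## Reader-study statistics

Scores 1–3 binarize to absence, 4–5 to presence.  Ground truth is the
unanimous binarized consensus per surface; non-unanimous or incomplete
surfaces go to an adjudication list, and adjudicated decisions may not
override unanimity (a decision for a unanimous surface warns and is
ignored).  Data cleaning drops surfaces whose tooth condition is `missing`
or `excluded` in any record; `restorated` and `support` teeth keep their
scores.  Which arm feeds consensus is a parameter (`unaided` in the demos);
with real panels the choice should be reported alongside results.

Accuracy is (TP + TN)/(TP + FP + TN + FN).  Cohen's kappa comes from the
2×2 table with chance agreement from the row/column marginals; the
degenerate all-one-cell table returns κ = 1.  Weighted kappa uses
disagreement weights (|i − j|/(k − 1))^q over the full 1–5 category set
(q = 2, quadratic, is the default reported scale; linear available); on a
binary scale both weightings reduce to Cohen's kappa.  Fleiss kappa requires
a constant rater count per item and reports per-category coefficients
κ_j = 1 − Σᵢ n_ij(m − n_ij) / (n·m(m−1)·p_j(1−p_j)) alongside the overall
coefficient.  Kappa confidence intervals use the large-sample standard
error √(p_o(1 − p_o)/(n(1 − p_e)²)).  The ordinal ROC uses the four
cutpoints of the five-point scale plus the trivial endpoints, with
trapezoidal area; this equals the tie-corrected pair-concordance
probability, and ties are handled by the 0.5 convention.  All of these are
implemented directly (per-category Fleiss components are not available in
standard libraries) and cross-checked in the test suite against
scikit-learn and statsmodels where overlaps exist, and against brute-force
double-sum / pair-enumeration oracles everywhere.

The published contingency counts of the three-observer, two-arm CBCT study
(19,936 surfaces) ship as input data; expanding them into a full rating
table fixes which observer errs on which surface by convention (marginal
counts do not identify it) while reproducing every printed count, metric and
kappa exactly.  Coefficients that depend on the unpublished raw ratings —
the study's Fleiss kappas, AUCs and pairwise weighted kappas — are *not*
reproduced; the machinery that would compute them is validated by the
oracle, null-simulation and parameter-recovery checks instead.

## Problem sizes in tests and the acceptance script

Phantom experiments run at 32³ voxels / 0.5 mm with a 3-level, 4-channel
network: overfitting two phantoms for 200 Adam steps (~1 min) and training
on 20 phantoms for 400 steps (~2 min) with evaluation on held-out
high-contrast lesions.  These sizes were chosen so the full pipeline is
exercised end to end in minutes on a single CPU; the null-simulation checks
average 10 independent replicates at the per-replicate sizes (n = 2000
ratings, 5000 items) so they test the statistic's centre rather than one
draw's noise.

## Known limitations

* The network is a desk-scale re-implementation: layer widths, input
  normalization and the classification-head details of the original
  clinical system are not public, so defaults here are declared choices,
  not reconstructions.
* NumPy training is single-threaded-friendly but slow beyond ~64³ inputs or
  ~10⁵ parameters.
* Lesion surface attribution (mesial vs distal) exists only as phantom
  ground truth; it is not computed from predicted masks.
* DICOM writing, panoramic reformats and viewer tooling are out of scope.
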