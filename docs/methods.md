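# Methods

## Problem and pipeline

`gtvseg` automates gross-tumor-volume (GTV) contouring on diffusion-weighted
MR volumes (DWI), where cervical tumors appear as bright regions on darker
pelvic anatomy. One case is a 3D DWI volume plus a binary reference mask of
identical geometry. The pipeline:

1. **Preprocessing.** Each 64×128×128 volume is cropped (no resampling) to a
   fixed region of interest chosen so that every tumor of the cohort lies
   inside it, yielding a 64³ grid (32³ in the desk preset). Each case is then
   z-scored over its whole 3D grid: `out = (in − mean)/σ`, population σ
   (divide by N). The population/sample distinction is numerically immaterial
   at N ≥ 32³ but is fixed so tests are exact.
2. **Training.** A 2D U-Net (per-slice) and a 3D U-Net (per-case) are trained
   with a soft-Dice objective under three cross-validation partitions: two
   distinct 3-fold splits and one 9-fold split. Within a scheme, the model
   for fold *f* trains on the other k−1 folds and predicts fold *f*, so every
   case receives exactly one out-of-fold prediction per scheme — and is never
   predicted by a model that saw it.
3. **Fusion.** The six binary predictions per case (3 schemes × 2
   architectures) are summed voxelwise; a voxel is tumor in the final mask
   iff its vote count ≥ 3. The tie at exactly 3 counts as tumor (the
   inclusive reading of a "threshold of 3"); the threshold is configurable.
4. **Evaluation.** DSC = 2|A∩B|/(|A|+|B|) on whole-case grids; Hausdorff
   distance (HD) as the symmetric max-min over mask voxel coordinates,
   reported in mm.

## Network architecture

Both U-Nets share one topology, generic over spatial rank. Contracting path:
`depth` blocks of *BatchNorm → LeakyReLU(α = 0.2) → stride-2 convolution
(kernel 4, padding 1)*, halving each extent per block; a 64-edge input
reaches a 1-edge bottleneck after six blocks. Expanding path: `depth` blocks
of *BatchNorm → skip-concatenation with the equally-sized contracting
feature map → ReLU → stride-2 transposed convolution*, doubling each extent;
dropout (rate 0.5) acts on the intermediate expanded feature maps. The first
expanding block has no skip (its only size peer is the bottleneck itself).
The transposed kernel is 2×2 (padding 0) in 2D and 4×4×4 (padding 1) in 3D —
the asymmetry is kept as specified upstream and both kernels double each
extent exactly; either can be overridden in `UNetConfig`. The head emits one
channel through a sigmoid. Channel widths double from `base_channels` up to
`channel_cap`; widths are not dictated by the architecture description, so
they are configuration, with small defaults for CPU use.

The engine is implemented directly in NumPy (`_nn.py`): im2col/col2im-based
strided convolutions (a transposed convolution is the exact adjoint of a
convolution, so the two share primitives), batch normalization with running
statistics frozen at inference, inverted dropout, Adam, and hand-derived
backpropagation. Gradients are verified against finite differences in the
test suite. Everything is float32; training and inference are fully
deterministic given the configured seed (inference additionally independent
of batch composition).

### Objective

Soft Dice per sample: `1 − (2Σpt + ε)/(Σp + Σt + ε)` with ε = 1. This is the
standard differentiable relaxation of the DSC; ε both smooths the
denominator and keeps the loss defined for empty targets. In 2D the loss is
per-slice, in 3D per-case, averaged over the batch.

### Defaults that matter

| parameter | default | note |
|---|---|---|
| LeakyReLU α | 0.2 | contracting path only; expanding path uses ReLU |
| dropout rate | 0.5 | expanding path |
| optimizer | Adam, lr 0.001 | study-scale setting |
| epochs | 5 (2D) / 70 (3D) | study-scale; desk preset uses 3 |
| batch size | 64 | desk: 32 (2D) / 2 (3D) |
| validation | 25 % of the augmented pool | held out per augmented sample; a per-case holdout is available via the pool construction |
| binarization threshold | 0.5, inclusive | per-member, before voting |
| vote threshold | 3 of 6, inclusive | configurable |

## Augmentation

Training data are expanded by a Cartesian grid of in-plane transforms:
shifts of {−2, 0, +2} pixels on each in-plane axis, rotations of
{−5°, 0°, +5°} about the slice center, and an optional left–right flip —
3·3·3·2 = 54 transforms including the identity. A transform is applied
identically to every slice of a case (and to its mask), so the 2D and 3D
models see geometrically consistent data; the through-slice axis is never
transformed or resampled. Rotation interpolates linearly for images and
nearest-neighbor for masks (re-binarized at 0.5); shifts fill with 0 for
masks and with the image minimum for images to avoid bright border
artifacts. Applying transforms composed as rotate → shift → flip makes the
identity exact and the flip an involution.

## Fold schemes

Partitions are seeded uniform shuffles with round-robin assignment, so fold
sizes differ by at most one: for 98 cases, 3-fold gives {33, 33, 32} (65 or
66 training cases per rotation) and 9-fold gives {11×8, 10} (87 or 88). The
two 3-fold schemes differ only in their seed; the pipeline verifies they
produce distinct partitions and re-seeds the second otherwise. No
stratification by tumor size is applied.

## Hausdorff distance

Directed distances are read off an exact Euclidean distance transform of
the opposing mask, so cost scales with the grid, not |A|×|B|; the point set
is all mask voxels, not a surface extraction. Two mm conversions:

* `anisotropic` (default) — axes scaled by their own voxel spacing
  (slice thickness 5–8 mm vs ≈1.25–1.64 mm in-plane), geometrically correct;
* `paper_scalar` — voxel-index distance multiplied by the scalar in-plane
  pixel size, for compatibility with reports that ignore anisotropy.

An empty prediction has no defined HD; it is recorded as missing with a
warning (DSC is 0), never fabricated. Cohort summaries use Tukey hinges
(median of halves) for quartiles and the 1.5×IQR box-plot convention for
outliers; the relative tumor volume is the per-case sum of cross-sectional
mask areas (mm²) normalized to the cohort maximum — an area-sum definition
kept deliberately, units included.

## Phantom generator

The generator emulates the salient structure of pelvic DWI, not its
physics: an ellipsoidal bright tumor (intensity 900) on darker anatomy
(100), additive Gaussian noise (σ = 20; Rician magnitude noise is out of
scope), optional low-intensity necrotic cavity (250) inside the tumor that
*remains labeled tumor* in the reference mask, an optional hematoma blob
touching the tumor at 95 % of tumor intensity, and up to two bright
distractor blobs nearby. Membership is by voxel-center inclusion, which
makes a brute-force oracle exact. Tumor major-axis diameters are sampled
from 10–60 mm (desk: 12–28 mm), deliberately covering the sub-40 mm regime
where overlap metrics are fragile; necrosis and hematoma prevalences default
to 27/98 and 16/98. Masks are pure functions of the sampled geometry —
never of the noise draw — so noise level cannot change ground truth.

What passing on phantoms does **not** show: robustness to scanner/protocol
variability, partial-volume boundaries, motion, coil inhomogeneity, or
anatomies where tumor intensity overlaps normal tissue more subtly than the
modeled distractors. Phantom results validate the machinery, not clinical
performance.

## Scale presets and problem sizes

Study-scale training (64³, 54× augmentation, 70 epochs) is GPU-scale. The
`desk` preset used by the test suite and the acceptance script runs the
complete pipeline on CPU: 12-case phantom cohorts at 32×64×64 cropped to
32³, depth-5 nets with base 8 channels, an 18-transform shift/flip subgrid
(3·3·2; rotations dropped to keep the augmented pool proportionate), 3
epochs, lr 0.01 (2D) / 0.03 (3D), batch 32 (2D) / 2 (3D). These values were
chosen so the small nets demonstrably converge (out-of-fold DSC ≈ 0.9 on
phantoms) while a full six-member run stays around five minutes on one CPU
core.

## Numerical and degenerate-input choices

* Constant volumes (σ = 0) are rejected by normalization, not silently
  passed through.
* int16 raw export refuses out-of-range or non-integral values rather than
  clipping; raw blocks are little-endian, slice-major, with a JSON sidecar
  (shape, dtype, spacing) making files self-describing.
* Dice of two empty masks is an error (0/0), as is HD with any empty mask.
* Batch-norm ε = 1e-5, momentum 0.9; running statistics make inference
  deterministic and batch-independent.
* Weight init: He-scaled normals from the config seed; all randomness
  (init, shuffling, dropout, fold assignment, phantom sampling) descends
  from explicit seeds, with per-stage seeds split from the master seed.

## Known limitations

* The NumPy engine is single-threaded and CPU-bound; study-scale settings
  are impractical with it (by design — the desk preset exists for that).
* BatchNorm with 3D batch size 2 is noisy; it is kept because the
  architecture specifies batch normalization, but it is the main reason the
  desk 3D members trail the 2D members in out-of-fold DSC.
* With near-ceiling members on easy phantoms, majority voting cannot be
  expected to beat the single best member at the third decimal; the
  ensemble's advantage is robustness (see the degraded-member test), which
  is the regime the method targets on heterogeneous clinical data.
* `paper_scalar` HD uses the row-axis pixel size and assumes square in-plane
  pixels.
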