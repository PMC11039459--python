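# Methods

## Problem and model

`topoct` reconstructs a coarse 3D CT volume from the two scout projections
(topograms) acquired before every CT scan — one anterior-posterior (AP), one
lateral (LAT) — so that organ-aware quantities (e.g. per-view dose surrogates)
can be estimated *before* the volumetric scan. Reconstruction from two views
is severely ill-posed, so the mapping is learned adversarially: a generator
G maps the projection pair x = (x_ap, x_lat) to a volume y' = G(x) in
normalized attenuation units, and a 3D patch discriminator D scores volumes
as real or generated (least-squares GAN objectives, targets 1/0).

Plain GAN training optimizes voxel statistics and routinely produces
plausible-looking volumes with wrong anatomy. Two additional terms inject
anatomical structure:

* **Segmentation guidance** `L_s`: a 3D U-Net organ segmenter φ_s
  (background / lung / liver / bone), pretrained on labeled volumes and
  frozen, is applied to both y and y'; the mean soft Dice loss
  `1 − 2Σ(ab)/(Σa + Σb + ε)` over the three foreground organs penalizes
  anatomically wrong reconstructions. Gradients flow into y' only.
* **Perceptual guidance** `L_p`: both volumes are sliced along the vertical
  axis, each slice replicated to 3 channels and embedded by a fixed 2D
  convolutional feature pyramid; feature differences over the first four
  pyramid levels are summed over channels and averaged over slices.

Together with the voxel MSE `L_r`, the projection-consistency MSE `L_proj`
(AP and LAT forward projections of y and y'), and the adversarial term, the
generator objective is

    L_G = λ_gen·L_gen + λ_r·L_r + λ_proj·L_proj + λ_s·L_s + λ_p·L_p

with defaults λ_gen = 0.1, λ_r = 10, λ_proj = 10, λ_s = 2.0, λ_p = 0.5.
Setting λ_s = λ_p = 0 recovers the three-term baseline objective.

## Fan-beam geometry and the lifting operator

The scanner model is per-slice fan-beam: a point source rotates about the
vertical axis (AP at 0°, LAT at 90°), with source-to-isocenter distance
SID = 595 mm and source-to-detector distance SDD = 1085.6 mm (Siemens
Somatom Force values). Two operators derive from one geometry object:

* **Forward projector** (ray-driven, Joseph-style): for each detector
  channel, samples along the source-channel ray at half-voxel steps with
  bilinear in-slice interpolation, scaled by the step length in mm. Used for
  topogram simulation and `L_proj`.
* **Backprojection lifting** T (pixel-driven): each in-slice pixel center is
  projected along its ray onto the detector; the continuous detector
  coordinate splits unit weight over its two neighboring channels (linear
  interpolation). T is a sparse (n², n_detector) matrix with row sums of 1
  for pixels that project inside the detector and all-zero rows otherwise.
  Applied per (channel, z) row, T lifts 2D feature maps into the 3D grid
  inside the generator; the LAT matrix is built directly in the common
  frame, so lifted AP and LAT feature volumes share one coordinate system.

Both operators are fixed sparse matrices; their adjoints are exact
transposes (inner-product identity to 1e-10 in double precision), and the
lifting in the generator uses exactly the geometry module's matrices — no
learned projection.

Choices the scanner protocol leaves open (documented as package decisions):
flat detector rather than an arc; detector pitch chosen so the detector
exactly covers the magnified field of view; pixels projecting outside the
detector receive zero weight rather than clamping; the forward projector is
ray-driven while lifting is pixel-driven, intentionally unmatched (each
operator's adjoint is its own transpose). The 920-ray scanner fan can be
simulated by configuring `n_detector=920`; training-resolution operators
default to the network's projection resolution so that T stays compatible
with feature-map sizes.

**Units of `L_proj`.** Raw fan-beam line integrals of a [0,1]-normalized
volume are O(100) in mm units; with λ_proj = 10 they would dominate every
other term. The projection loss therefore works in average-attenuation units
(line integral divided by the in-slice field-of-view extent in mm), which
makes projection-space and voxel-space errors commensurate and keeps the
published λ balance meaningful.

## Generator, discriminator, segmenter

* **Generator**: two independent 2D U-Net pathways (one per view), n_levels
  resolution levels (default 4 full-scale, 3 at desk scale), channels
  base·2^level capped at 8×base, instance normalization, ReLU. At every
  decoder level the 2D features are lifted with the level-resolution system
  matrix; AP and LAT lifted stacks are fused by elementwise addition; a
  single 3D decoder (nearest-neighbor upsampling + conv, skip connections to
  the fused levels) emits one channel through a sigmoid.
* **Discriminator**: 3D patch classifier in the pix2pix lineage — three
  stride-2 conv blocks (kernel 4, leaky-ReLU 0.2, instance norm after the
  first block) and a 1-channel convolutional head; one score per
  receptive-field patch, no global pooling.
* **Segmenter φ_s**: vanilla 3D U-Net with exactly five downsampling levels
  and a 4-class softmax head. Pretrained with mean foreground soft Dice
  against one-hot labels (Adam, lr 5e-4); frozen during GAN training
  (verified bitwise in tests).
* **Feature extractor φ_p**: a fixed 4-level 2D conv pyramid (stride-1 stem,
  three stride-2 stages, ReLU). Default weights are seeded random — a
  random fixed pyramid is a valid perceptual metric for the loss properties
  used here — and a pretrained-weight array file can be loaded instead for
  full-scale runs.

## Numerics

All networks run on a compact numpy reverse-mode autodiff written for this
package (`topoct.nn`): convolution is computed offset-wise as channel-mixing
matrix products on strided slices; gradients of every primitive are
validated against central finite differences in the test suite. The sparse
lifting and projection ops backpropagate through the exact operator
transposes. Parameters are float32; geometry operators are built in float64
and cast where they enter networks.

Optimization follows GAN convention: Adam with betas (0.5, 0.999) and
lr 2e-4 for both G and D, one discriminator step per generator step (real
batch vs detached fake, then the generator step through a fresh
discriminator pass), batch size 1. The segmenter uses betas (0.9, 0.999).
No learning-rate schedule. Training is bitwise deterministic given (config,
seed): parameter initialization comes from seeded generators, the data order
is fixed, and no other randomness enters the loop; checkpoints store
parameters, optimizer state, config and corpus constants, so a resumed run
reproduces the interrupted run's logged losses exactly.

Degenerate cases are pinned down explicitly: Dice terms use ε = 1e-6 and
report 1.0 for a class absent from both masks, 0.0 when absent from exactly
one; PSNR reports infinity on identical volumes; the Dice expression with
plain-sum denominator is exactly zero on identical hard masks, while for
identical *soft* probability maps it equals the map's self-overlap deficit —
tests assert each case as such.

The perceptual loss follows the squared-L2 feature difference of the model
definition; an L1 variant is available behind `perceptual_metric="l1"`
because prose descriptions of such losses often mean L1 aggregation.
Slices are axial planes (perpendicular to the vertical z axis), and the loss
averages over slices so it is independent of batch and grid size.

## Preprocessing

Volumes are clipped to the fixed window [−1024, 3071] HU (the standard
12-bit CT range; the normalization must be shared by every volume in a run
and is stored in the config) and mapped affinely to [0, 1]; grids are
center-cropped / air-padded to the training size; resampling is trilinear.
Topograms are simulated by forward projection of the normalized volume and
divided by a single run-level constant — the maximum projection value over
the training corpus — rather than per-image min-max, which would destroy
attenuation-magnitude cues; the constant is stored in the config/checkpoint
and required at inference.

## Synthetic corpus

The phantom generator emulates the structure of a thorax CT with organ
labels: a soft-tissue body (elliptical cross-section) on air, two lung
ellipsoids (−800 ± 50 HU), one liver ellipsoid (60 ± 15 HU), a vertical
spine cylinder and 4–8 rib arcs (bone, 700 ± 100 HU), mild Gaussian voxel
noise (σ = 5 HU), all primitives drawn per-phantom from configured fraction
ranges and painted into both the HU volume and the label mask. Organ
placement is retried until contained in the body and errs after bounded
retries. Every phantom satisfies label–HU consistency (lung < −500 HU,
bone > 300 HU) by construction.

What the corpus does *not* model: real anatomical texture, pathology,
inter-organ soft-tissue contrast beyond the liver, scatter/noise physics in
projections, or the domain gap between simulated and scanner topograms.
Passing tests therefore demonstrate that the pipeline's operators, losses,
optimization and evaluation behave correctly and that anatomy guidance has
the expected direction of effect on organ overlap — not that clinical-image
quality figures transfer to real data.

## Desk-scale study conditions

The reference schedule (grid 128 at 2.5 mm, 100 GAN epochs, 200 segmenter
epochs, base 64 channels) targets GPU hardware. All shipped experiments use
the desk profile, chosen so the full pipeline runs on one CPU core: grid 32³
at 10 mm voxels (same 320 mm field of view), generator/discriminator base 8,
segmenter base 8, extractor base 4, batch 1, the same λ defaults. Corpus
sizes and epoch counts per experiment are stated with each test and in the
acceptance script; thresholds (held-out segmenter DSC > 0.9, halving of L_r
over ten epochs, anatomy-guided DSC exceeding the baseline in at least 2 of
3 seeds, S-analog ≥ M-analog mean DSC) are unchanged from the full-scale
statements.

Two segmenter-stage settings are adapted to the desk iteration budget
(≈300–600 Dice iterations instead of ≈2×10⁴): the learning rate is raised
from the reference 5e-4 to 2e-3, and a 0.3-weighted voxel-wise
cross-entropy term is added to the Dice objective. Pure Dice at short
schedules lets the lowest-contrast class (liver, 60 ± 15 HU inside
40 ± 20 HU soft tissue) collapse — its softmax channel saturates toward
zero and the class never recovers — in roughly half of initialization
seeds; the cross-entropy term is the standard stabilizer for exactly this
failure mode and restores smooth seed-robust convergence. The full-scale
configuration keeps the reference pure-Dice recipe (`seg_ce_weight = 0`),
and the Dice term alone remains the logged and thresholded quantity.

## Evaluation protocol

PSNR (data range 1.0 on normalized volumes), SSIM (3D, Gaussian-weighted
11-wide window, σ = 1.5; cross-checked against slice-wise 2D SSIM), RMSE
reported in HU by inverting the normalization window. Organ overlap uses the
Dice coefficient under a dual-reference protocol: the frozen segmenter
labels the reconstruction, and the result is scored against (a) the
phantom's true label mask — the analog of manual annotation (DSC_M) — and
(b) the segmenter's labeling of the true volume (DSC_S). DSC_S removes the
segmenter's own error from the comparison and is expected to read at least
as high as DSC_M on average.

## Known limitations

* The numpy backprop engine is single-threaded and memory-bound; full-scale
  128³ training is out of reach on CPU, so published full-scale figures are
  not reproduced here — the package reproduces the method and its
  qualitative behavior at desk scale.
* The perceptual extractor's random weights make `L_p` a generic multi-scale
  structure metric rather than a semantics-aware one; loading pretrained 2D
  weights is supported but not bundled.
* Fan-beam only (no cone-beam or helical geometry, no detector arc, no
  polychromatic/scatter physics).
* The phantom corpus has no unlabeled "other" anatomy beyond the body and
  soft-tissue background (heart, vessels etc. are not simulated), so the
  segmenter's task is easier than on clinical data.
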