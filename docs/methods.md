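# Methods

`bonesct` re-implements, as a tested pipeline on synthetic data, a
feasibility analysis of deep-learning synthetic CT (sCT) for metastatic
bone: paired dual-echo gradient-echo MR and CT volumes of a bone with a
lytic, blastic or mixed lesion are simulated; CT-to-MR alignment is
initialized by rigid ICP on bone surfaces; a patch-based 3D UNet-like
network is trained to translate the two MR echoes into CT under
leave-one-out cross-validation (LOOCV); and sCT is scored against CT with
the MAD / MD / DSC / surface-RMSD suite and cohort summarization.

## Digital phantom

The phantom is a stylized long bone in a water bath, rendered on a
`64 × 64 × 64` grid with `1 × 1 × 2 mm` voxels (matching a typical
T1-weighted dual-echo protocol's resolution). Concentric compartments —
cortical shell (3 mm), cancellous interior, medullary (marrow) core,
wrapped in muscle and subcutaneous fat — form a flared tube with an
elliptical cross-section (ratio 0.7) and a trochanter-like lateral bump.
The ellipse and bump are not decoration: they remove the rotational
near-symmetry of a plain tube, which is what makes rigid surface
registration well-posed on this geometry.

Lesions are spheres (radius drawn from 0.45–0.7 of the inner bone radius)
placed in the bone interior: osteolytic lesions replace bone with
soft-tissue-like material, osteoblastic lesions with dense sclerotic
material, mixed lesions are half/half along the bone axis. An optional
cortical breach carves the shell window adjacent to the lesion. The
default nine-case cohort reproduces the 3 lytic / 4 blastic / 2 mixed
composition of the clinical cohort this pipeline emulates; per-case
anatomy (radius, shell thickness, flare, lesion placement) is randomized
from recorded per-case seeds, and a fixed master seed reproduces the
cohort bitwise.

**Bone mask definition.** The ground-truth bone mask is the whole
anatomical bone — cortical shell, cancellous interior, medullary cavity
and any intra-bone lesion — mirroring a clinical bone segmentation. This
matters for evaluation: the 150-HU extraction step exists precisely to
separate ossified tissue from marrow and lytic tissue *within* the
segmented bone; a mask containing only above-threshold tissue would make
that step vacuous and every threshold-based score trivially high.

**CT rendering.** Per voxel, HU ~ Normal(mean, SD) of its tissue class,
then a 0.5-voxel Gaussian point-spread blur creates partial-volume
boundary voxels. Defaults (HU mean ± SD): cortical 1200 ± 50, cancellous
300 ± 50, marrow −50 ± 20, muscle 40 ± 15, fat −100 ± 20, water 0 ± 10,
lytic lesion 50 ± 30, blastic lesion 700 ± 60 — chosen to straddle the
150-HU threshold (cortical/cancellous/blastic above; the rest below).
With noise and blur disabled the rendering is an exact lookup, which
several tests rely on. A lesion's `hu_delta`, when given, overrides the
lesion mean relative to the cancellous base.

**MR rendering.** The steady-state spoiled gradient-echo signal

S(TE) = PD · sin α · (1 − E1)/(1 − cos α · E1) · e^(−TE/T2\*) ·
|(1 − ff) + ff · e^(i·2π·Δf·TE)|,  E1 = e^(−TR/T1)

is evaluated per tissue with TE1/TE2/TR = 2.1/4.2/7 ms, flip α = 10° and
a fat–water shift Δf = 220 Hz (≈3.5 ppm at 1.5 T), so TE 2.1 ms sits near
opposed phase and TE 4.2 ms near in phase — the characteristic dual-echo
contrast the network receives. Tissue PD/T1/T2\*/fat-fraction values are
plausible 1.5-T stand-ins (config-exposed), not measured literature
values. Magnitude noise is Gaussian rather than Rician: at the simulated
SNR the difference is immaterial, and Gaussian keeps the noiseless limit
exact. Geometry, CT noise and MR noise each draw from independent seeded
streams, so toggling one never changes another.

**What the phantom does not emulate:** patient-realistic anatomy, bias
fields, motion or susceptibility artifacts, Rician noise floors, scanner
reconstruction filters, and the hyperintense device fluid that motivates
the 95th-percentile clip (the clip itself is exercised, its cause is
not). Green tests therefore demonstrate that the pipeline's machinery is
correct and that learning occurs on well-posed data — not that clinical
accuracy numbers transfer.

## Preprocessing

MR magnitudes are clipped at the per-volume 95th percentile (linear
interpolation between order statistics) and mapped affinely to [−1, 1]
with 0 → −1: magnitude data have a physical zero, so the lower anchor is
0, not the volume minimum. A constant-zero volume is rejected as corrupt
rather than silently normalized. CT is mapped affinely from the fixed
range [−1024, 3071] HU to [−1, 1] (values outside are clipped first);
this map is exactly invertible and is how network outputs return to HU.

Training pairs are 24³-voxel patches. By default 80 % of patches are
drawn from origins whose window intersects the bone mask (the evaluation
region is bone) and 20 % anywhere; sampling is with replacement.
Augmentation — random sagittal/coronal flips (p = ½ each) and a rotation
drawn uniformly in ±45° about the feet–head axis — is applied to whole
volumes *before* patch extraction (rotating a 24³ patch would lose its
corners), with linear interpolation for images and nearest-neighbour for
masks, identically across both MR channels, the CT target and the masks.

## Rigid registration

Bone masks become surface clouds (centers of voxels with ≥1 of 6 face
neighbours outside the mask, in mm, honoring anisotropic spacing). ICP
alternates nearest-neighbour correspondence (one-directional,
moving→fixed, no trimming; KD-tree, ties to the lowest index) with a
closed-form least-squares rigid fit via cross-covariance SVD with a
reflection guard. Convergence: RMS correspondence distance changing by
< 1e−3 mm (config) or 100 iterations.

Vanilla ICP from identity is unreliable here: a 20-mm offset or a small
rotation about the bone's long axis lands in a shallow local minimum.
Two standard robustifications are built in: the translation is seeded by
centroid alignment, and ICP restarts from rotations of
0°, ±10°, ±20°, ±30° about the fixed cloud's principal axis (the long
axis of the bone, where the ambiguity lives), keeping the start with the
lowest final RMS. With these, recovery of random misalignments up to 30°
rotation / 20 mm translation on noiseless phantom surfaces is exact to
< 0.1° and < 0.1 mm (tests use a tighter 1e−6 mm tolerance to let the
RMS collapse fully). Resampling onto the fixed grid uses cubic B-spline
interpolation for images and nearest-neighbour for masks, with declared
background values (−1024 HU for CT, 0 otherwise). Only the rigid stage is
implemented; a deformable refinement can be inserted externally between
registration and evaluation. The one-directional, untrimmed
correspondence is adequate for clean, fully overlapping phantom surfaces
and is a documented limitation for real partially-overlapping data.

## Network and training

A 3-level 3D UNet-like encoder–decoder maps 2-channel (dual-echo) 24³
patches to 1-channel CT patches on the normalized scale: two 3×3×3
conv + ReLU layers per level, 2×2×2 max-pool down, 2×2×2 transposed-conv
up, skip concatenations, and a linear 1×1×1 head. Channel width doubles
per level from `base_filters` (32 at full scale; 8 in the desk-scale
configuration used by the tests, ≈85 k parameters). Blocks deliberately
omit normalization layers: inputs are bounded in [−1, 1], the network is
small, and a lean layer set keeps the hand-written implementation
verifiable — the forward/backward stack is numpy plus numba-jitted
direct-convolution kernels (the input gradient is computed as a gather
convolution of the padded output gradient with the channel-transposed,
spatially flipped kernel), and the test suite checks every layer's
gradients against central differences at double precision.

Training minimizes the L1 distance between predicted and true normalized
CT patches with Adam (default learning rate 1e−4, β = 0.9/0.999). Per
epoch, each training case is augmented as a whole volume and re-sampled
for patches; minibatches are shuffled; the checkpoint with the best
validation L1 (computed on a fixed patch set from the held-out validation
case) is returned. All randomness — weight init, augmentation, patch
sampling, shuffling — flows from a single seed, so training logs are
bit-reproducible. A non-finite loss aborts with a diagnostic rather than
continuing silently.

LOOCV over n cases builds n models: fold i tests case i, validates on
case (i+1 mod n), trains on the remaining n−2. An untrained
(freshly-initialized) copy of the network is evaluated on each fold's
test case as the learning-sanity baseline. Full-volume inference tiles
patches at stride 12 (half a patch) and averages overlaps with
centre-weighted (separable triangular, strictly positive) weights,
down-weighting patch borders where the network has the least context;
because the weighted average is normalized, a constant network output is
still preserved exactly, to 1e−6 HU. The average is mapped back to HU
and clipped to [−1024, 3071].

**Desk-scale configuration.** The package's default experiment — nine
64³ phantoms, 8 base filters, 5 epochs, 16 patches per volume, batch 8,
all patches bone-intersecting — is sized to run the full nine-fold LOOCV
in well under half an hour on a single ordinary CPU core. At this scale
only ~70 optimizer steps are taken per fold, so the desk-scale learning
rate is raised to 3e−3 and patch sampling concentrates entirely on the
bone-intersecting windows that the evaluation scores; the 1e−4 learning
rate and the 80/20 bone/anywhere sampling split remain the full-scale
defaults, where abundant steps amortize a small step size and broader
sampling. No claim is made that desk-scale phantom metrics match
clinical-scale accuracy; the LOOCV check asserts only that learning
beats the untrained baseline on held-out bone extraction.

## Evaluation

Within a region mask, MAD = mean |sCT − CT| and MD = mean (sCT − CT)
(sign fixed as sCT minus CT, so negative MD means the sCT underestimates
HU). Bone is extracted from each image as voxels ≥ 150 HU (inclusive;
strictness is a documented choice) inside the mask; DSC = 2|A∩B|/(|A|+|B|)
and the surface RMSD are computed between the two extractions. The RMSD
is directed — from each boundary voxel of the sCT-derived bone to the
nearest boundary voxel of the CT-derived bone, root-mean-squared — with a
symmetric variant behind a flag; distances come from an exact Euclidean
distance transform sampled with the voxel spacing, and agree with a
brute-force all-pairs computation to 1e−9 on randomized instances.

The lesion region uses the undilated lesion mask for MAD/MD/DSC; for the
surface distance only, the mask is dilated by a 3-cm physical margin
(all voxels within 30 mm of the mask, anisotropy-aware), so the relevant
bone surface around the lesion is in scope. Degenerate cases are flagged,
never zeroed: Dice of two empty extractions is 1 (agreement on absence)
with a warning; a region with no extracted bone on either side yields
NaN DSC/RMSD and a `flagged` report entry. Cohort summaries are
arithmetic means with sample (n−1) standard deviations; with one value
the SD is NaN.

## Numerical and design notes

- Percentile definition: numpy's linear interpolation between order
  statistics; percentile dialects differ enough to matter at p95.
- The per-volume clip (rather than a cohort-level one) is forced by
  single-case inference: a new case must be normalizable alone.
- Patch tiling uses uniform overlap weights, not Gaussian feathering,
  to keep constant-preservation exact.
- `dice` on shape-mismatched inputs, resampling with an unknown
  interpolator, lesions centered outside bone, empty masks and empty
  training sets all raise with specific messages naming the offender.
- Model checkpoints serialize weights plus both configs and the
  normalization convention; reloaded models predict bit-identically.

## Known limitations

- Phantom realism as listed above; in particular all misalignments are
  rigid by construction, so the deformable stage of a clinical pipeline
  is out of scope (a hook point exists between registration and
  evaluation).
- One-directional untrimmed ICP correspondences assume clean, fully
  overlapping surfaces.
- The numpy network is CPU-bound and desk-scale; it is an exact but
  small-scale stand-in for GPU-scale training, and phantom metric values
  should not be compared with clinical ones.
- The multi-start ICP assumes the dominant registration ambiguity is
  rotation about the surface's principal axis — true for long bones and
  this phantom, not for arbitrary shapes.
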