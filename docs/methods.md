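# Methods

This note records the model, the numerical and design choices, and what
the package's synthetic experiments do and do not demonstrate.

## Problem and representation

A skull is represented as a binary occupancy grid (1 = bone) with
physical voxel spacing (sx, sy, sz) in mm and a world origin. Grid axes
are (X, Y, Z) with Z craniocaudal and Y anterior; indexing is 0-based.
The reconstruction task is shape inpainting: given a defective
occupancy grid, predict the intact one; the implant is then the Boolean
difference between the completed and (tolerance-scaled) defective
models. The reference protocol works at 512×512×384 with a
128×128×96 low-resolution stage; every component here is fully
convolutional and resolution-agnostic (any grid with dims divisible
by 8 for the low-resolution networks), and the package's own
experiments run at desk scale — 32×32×24 to 64×64×48 grids — so that
training and tests complete in CPU minutes.

## Volume normalisation

* **Bone extraction**: closed Hounsfield window, voxel = 1 iff
  lo ≤ I ≤ hi, defaults [1200, 1817] HU. Endpoints are inclusive
  because the protocol states a closed interval.
* **Frankfort crop**: all bone below a per-volume craniocaudal slice
  index is zeroed. The index is configuration — no automatic landmark
  detection.
* **Craniocaudal resampling**: CT stacks with slice intervals of
  0.3–1.25 mm are normalised to a fixed slice count by a 1-D windowed
  sinc (Lanczos) kernel along Z only. Kernel order a = 3 (the protocol
  does not state one; 3 is the common default), out-of-range taps are
  clamped to edge values, and tap weights are renormalised to sum to 1
  so constants are exact fixed points. Binary volumes are interpolated
  as reals and re-thresholded at 0.5.
* **Resolution pairing**: the low-resolution member of each pair is
  block-majority downsampling of the high member (factor 4; ties —
  exactly half the block — count as bone, keeping the rule
  deterministic and symmetric).
* **Raw-uint8 dialect**: 1 byte/voxel, X-fastest order, JSON sidecar
  `{dims, spacing, origin}`. NIfTI and NRRD round-trip through nibabel
  and SimpleITK.

## Synthetic phantoms

The phantom generator replaces patient data everywhere. A phantom is
the set of voxel centres between two concentric ellipsoids (outer
semi-axes (a, b, c), inner = outer − thickness), with the right half
scaled by (1 + asymmetry) — real skulls are not sagittally symmetric —
cropped below a base plane at a fixed fraction of the grid height.
Defaults: a ∈ [60, 75] mm, b ∈ [72, 90] mm, c ∈ [52, 64] mm (adult
cranial-vault proportions), thickness ∈ [4.5, 8] mm (adult calvarial
bone), asymmetry ∈ [0, 0.08], base-plane fraction ∈ [0.25, 0.35],
64×64×48 grid over a fixed 192×192×153.6 mm field of view. The
implicit-surface definition gives an analytic volume oracle,
(4/3)π(abc − a′b′c′), used in tests.

One rasterisation detail: a wall thinner than the voxel pitch would
discretise into a sieve of diagonally-touching voxels. The rasteriser
therefore always unions in the one-voxel boundary layer of the outer
solid, so the discrete shell is closed at any resolution; at the
default resolution the shell is a single 6-connected component, and in
the degenerate thickness→0 limit it collapses to exactly that surface
layer.

What the phantoms do **not** emulate: sutures, facial and skull-base
anatomy, bone-density variation, scanner noise, and the irregular
borders of real craniotomies. Passing desk-scale tests therefore
demonstrates that the pipeline's mechanics (geometry, losses,
optimisation, Boolean extraction, metrics) are correct, not that the
trained toy checkpoints generalise to clinical data.

## Defect simulation

Masks come in four families: elliptical cylinder, ellipsoid, and two
unions — two cylinders with independent axes ("mixed"), and an
ellipsoid plus a cylinder sharing a centre ("hybrid"). The reference
renderings of the two compound families show silhouettes only; the
union-of-two-primitives composition is this package's concrete choice.
The leading in-plane diameter is uniform over [60, 120] mm, secondary
axes are scaled fractions of it, centres are uniform over the upper
skull (upper 45 % of the craniocaudal extent, central 80 % in plane),
and cylinder axes are uniform on the sphere. `apply_defect` partitions
intact bone exactly: defective = intact ∧ ¬mask, implant = intact ∧
mask. A defect is kept ("in range") iff the implant is non-empty, lies
at or above the base plane, and removing it does not fragment the
skull into more large 6-connected pieces than one beyond what the
intact model already had (the protocol never defines its out-of-range
rule; this is the package's testable formalisation). 25 variants per
skull is the reference default. Rotation augmentation yaws the volume
about Z in 2° steps, three per side plus the original (seven variants),
with nearest-neighbour resampling so grids stay binary.

## Network architectures and the parameter-total constraint

Both networks use only: 3×3×3 convs (stride 1, zero 'same' padding,
per-filter biases), 2×2×2 max pooling, ×2 nearest-neighbour
upsampling, ReLU/sigmoid, and summation junctions. No batch norm, no
concatenation.

**Completion (10 rows, 8,269 parameters).** Rows: conv 1→8;
conv+pool 8→8; conv+pool 8→4; conv+pool 4→4; two dilated (rate 2)
convs 4→4 with a residual sum closing the bottleneck; upsample+conv
4→4, 4→8, 8→8 with encoder summations; conv 8→1 + sigmoid; output
added to the input. The literal per-row sum is 7,397 — exactly one
3×3×3 conv 4→8 (872 parameters) short of the published total. The
only channel-mismatched skip is the 4-channel encoder map into the
8-channel decoder stage; giving that skip a 3×3×3 projection conv
makes every row keep its literal count and lands on 8,269 exactly.
The builder adopts that wiring. (The 1×1×1 alternative, 40 parameters,
does not reach the total; a "transition conv" at decoder entry would
change the first up-conv row's count. The published total thus pins
the wiring.)

**Enhancement (14 rows, 11,741 parameters).** A counting argument
shows no wiring of 14 *independent* biased 3×3×3 convs can reach the
total: with per-filter biases, total ≡ Σ(bias counts) mod 27, and
11,741 ≡ 23 (mod 27) while the 14 rows' channels sum to 85 ≡ 4.
Searching the family of wirings consistent with the two-branch
narrative leaves exactly one interpretable solution, which the builder
implements:

* rows 1–6 and 9–11 are the completion-style branch over the
  low-resolution completed model (with the same 872-parameter skip
  projection);
* row 7, the high-resolution branch's entry conv, **shares its
  weights** with row 1 (both rows see a raw skull occupancy volume, so
  a shared low-level feature extractor is natural; shared parameters
  are counted once);
* row 8 is the branch's conv+pool 8→8 down to half resolution, where
  the branches merge by summation;
* row 12 is **parameter-free** nearest-neighbour upsampling of the
  low-resolution branch to the merge resolution;
* row 13 is the post-merge upsample+conv 8→8, summed with the
  high-resolution stem output (the shallow U-Net skip); row 14 is the
  sigmoid head. The shallow branch's bottleneck has no dilation.

`craniofill net describe enhancement` prints this graph;
`net count` reports the computed totals, so any future wiring change
that breaks the constraint is visible rather than hidden.

Prediction threshold: voxel = 1 iff value ≥ 0.45 (the stated threshold
with the boundary included). Stage-1 post-residual values may exceed 1
on retained bone; they are not clipped — thresholding handles the
range.

## Engine

The networks run on a small numpy engine written for this package:
channel-last (N, X, Y, Z, C) float32 tensors, hand-written backward
passes, and Adadelta. Convolutions flatten the zero-padded grid to a
(voxels × channels) matrix so that each of the 27 kernel taps is one
contiguous row slice and one copy-free BLAS matmul; wrap-around rows
only ever read padding zeros or write rows that are cropped, so the
result is an exact 'same' convolution (gradients for weights, biases
and inputs use the same layout; layers applied to several inputs —
the shared stem — accumulate their gradients). Max-pool backward
routes gradients to the per-block argmax (first maximum on ties). All
forward/backward passes were verified against finite differences in
float64 to ~1e-5 relative error. Desk-scale training (40 volumes of
32×32×24) runs at a few seconds per epoch on one CPU core.

## Training recipe

Voxel-mean binary cross-entropy (predictions clipped to
[1e-7, 1 − 1e-7]; the mean-vs-sum choice only rescales Adadelta's
gradient statistics), Adadelta with ρ = 0.95, ε = 1e-6, lr = 1.0 (the
optimiser's selling point is not needing a tuned rate), per-epoch
reshuffling under a recorded seed, Glorot-uniform weight init (zero
biases) under a recorded seed, and best-validation-loss parameter
selection with ties to the earliest epoch. Reference batch sizes are
10 (completion) and 4 (enhancement); reference epoch counts at full
scale are 1,200 and 20. Stage 2 is trained with teacher forcing: the
true intact low-resolution model stands in for the stage-1 output.

### The desk-scale recovery experiment

The package's strongest self-check trains the completion network from
scratch and verifies that it actually learns to restore missing bone:
two phantoms, 30 simulated defects each, split per skull into 40
training, 10 validation and 10 held-out pairs at 32×32×24; batch
size 2 (small batches give more optimiser updates per epoch at
identical cost; the full-scale reference batch sizes are configuration
defaults, not desk-scale choices); 140 epochs with best-validation
selection. The held-out defects are never seen in training; each is
scored by the SDI between the predicted implant (thresholded
completion minus the defective input, no tolerance scaling) and the
ground-truth implant, and the suite asserts the mean exceeds 80 %.

Two experiment-design points matter here. First, the phantom wall
thickness is set to 2.3–3.0 voxel pitches (the default of
`phantom_training_samples`): at a 6.4 mm desk-grid pitch the
anatomical 4.5–8 mm wall is
sub-voxel and rasterises to a single-voxel sieve, a categorically
harder inpainting target than the reference low-resolution stage,
whose 5–7 mm walls span two to four of its ~2–3 mm voxels. Matching
the discrete wall-width regime — not absolute millimetres, which the
coarse grid cannot resolve anyway — is what makes the miniature
faithful. Second, the validation set must be large enough (10 pairs
here) for best-validation selection to track generalisation; a
handful of volumes yields a noisy BCE curve whose spurious early
minimum rolls back most of the training. Implant SDI remains a
demanding target throughout: every boundary voxel of a thin shell
patch counts.

## Metrics

* **SDI** is computed from voxel overlap counts; symmetric in P and G;
  undefined (error) when both sets are empty.
* **Directed Hausdorff** follows the stated max–min form from G into P
  over bone-voxel centres, computed exactly with a KD-tree; tests
  verify it against an all-pairs brute force. Lattice units by
  default — the HD-unit range (min spacing, ‖spacing‖₂) converts to
  mm — with an explicit mm mode and a clearly-labelled symmetric
  variant.
* **CVAI**: the measurement plane is the axial slice with the most
  implant voxels (ties → inferior-most). The midline point O is the
  centroid of the in-plane cross-section (the protocol never defines
  O's construction; the centroid is this package's stated choice, and
  O can be passed explicitly). Four rays at ±60° from the anterior
  Y-axis are sampled at quarter-voxel steps with bilinear
  interpolation, the outermost 0.5-crossing is refined by bisection,
  and lengths are Euclidean mm. The index formulas evaluate negative
  when the second diagonal is longer; magnitudes are reported (as the
  reference tables print) and signed values are retained in the record.

## Implant extraction

Tolerance scaling resamples occupancy under a uniform scale about the
occupancy centroid (nearest-neighbour, same grid; the centre is this
package's choice — the protocol says only "scale to 102 %").
Extraction is completed ∧ ¬scaled(defective). Post-processing is a
morphological opening with a voxel-radius ball followed by keeping the
largest 6-connected component(s); whether small secondary patches are
dropped is the `keep_components` parameter. Meshes are extracted by
marching cubes at level 0.5 on a ×2-replicated, zero-padded field
(replication removes the non-manifold checkerboard configurations thin
binary shells otherwise produce, so the STL is watertight), with
vertices mapped to mm.

## Known limitations

* Toy checkpoints trained on phantoms say nothing about clinical
  accuracy; the package reproduces the *method*, not the trained model.
* The enhancement wiring (shared stem, one parameter-free upsampling
  row) is the unique interpretable reading of the published totals,
  but the original implementation is not available to confirm it.
* Hausdorff on large dense grids builds a KD-tree over all bone
  voxels; fine for desk scale, memory-hungry at 512³.
* The CVAI midline construction (centroid-based O) is a convention;
  results for strongly asymmetric slices depend on it.
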