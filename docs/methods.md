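# Methods

## Problem and approach

Clinical applications in pelvic radiation oncology (bone-marrow-sparing
IMRT, radiopharmaceutical dosimetry) need each lumbar and thoracic vertebra
segmented *individually*. Plain semantic segmentation fuses neighboring
vertebrae near the processes; multi-network detect-then-segment pipelines
duplicate appearance learning across networks. `vertiseg` implements a
combined approach: one CNN with a shared encoder produces (a) a three-label
semantic segmentation of each volume patch and (b) a regression estimate of
up to three vertebra center locations per patch, and a classical
post-processing chain turns the accumulated outputs into an instance
segmentation.

All arrays are ordered (z, y, x) with z the cranio-caudal axis; spacings
and physical coordinates are (z, y, x) in mm. This convention is fixed
package-wide because mixed axial-first/z-first notations are a recurring
source of silent bugs in spine pipelines.

## Three-label encoding

Each instance is eroded with the 6-connected unit ball (the only discrete
ball of radius 1 in the voxel metric; the 26-connected cube would be radius
√3). The eroded core is the *body* label, the remainder the *boundary*
label; together they partition the original foreground exactly. Bodies of
adjacent instances are therefore always separated by at least two boundary
shells, which is what makes watershed-based instance splitting reliable.
The erosion radius (default 1 voxel) is configurable.

## Localization targets

For each 32×48×48 patch (50% overlap in all directions) the target is a
1×12 vector: three (z, y, x) offsets in mm from the patch center to the
body centers of a top/mid/bottom vertebra, plus three confidences. The body
center of an instance is the center of mass after a morphological opening
that removes the processes; the opening element is an ellipsoid of radius 1
voxel in z and 3 in-plane (the element size is not canonical — processes in
CT and in the phantom are 2–3 voxels thick — and is exposed in the API).

Mid-vertebra selection: one visible → it; two → the lower; three → the
middle; more than three → iteratively drop the lowest-confidence instance
(ties drop the topmost) until three remain, then take the middle.
Confidence of a present vertebra is the exact fraction of its total volume
inside the patch; an absent neighbor gets confidence 0 and a mirrored
position (mid + (mid − other neighbor)), falling back to a fixed z-shift
(`fallback_gap_mm`, default 30 mm ≈ one lumbar inter-center distance) when
there is no neighbor to mirror. Offsets are expressed in mm so the
regression target is independent of voxel anisotropy. The serialization
order (top offset, mid offset, bottom offset, conf top, conf mid, conf
bottom) is a package convention.

## Network

A 4-tier 3D U-Net-style encoder/decoder (two 3×3×3 convolutions per tier,
instance normalization, Leaky ReLU slope 0.01, 2× max pooling /
nearest-neighbor upsampling with skip concatenation) produces 3-class
logits at patch resolution. The regression head consumes the bottleneck
feature map: one 1×1×1 convolution, then four fully connected layers
(defaults 256, 128, 64, 12) with batch normalization and Leaky ReLU between
them. Channel widths (16→32→64→128 by default) and head widths are exposed
in `ModelConfig` and are deliberately small enough for CPU training.
Segmentation weights use Kaiming-normal initialization, the head
Kaiming-uniform.

The backend is a self-contained numpy implementation: convolutions are
evaluated as a single BLAS matmul over an im2col view; the input gradient
is computed as a convolution with the spatially flipped, channel-transposed
kernel (no scatter-add); optimization is Adam. Backpropagation was verified
against finite differences and by memorization tests. This keeps the
package free of GPU/framework dependencies at the cost of training speed,
which is acceptable because the package's validation strategy is built on
small synthetic phantoms.

Training: the segmentation branch minimizes a macro-averaged three-class
soft Dice loss (smoothing ε = 1e-5, intersection/sums pooled over batch and
space per class); batches draw at least half their patches from
vertebra-containing positions; augmentation applies random per-axis
rotations (±15°) and isotropic scaling (±25%) jointly to patch, labels and
offset vectors (rotations are performed in physical space, so anisotropic
voxels are handled correctly). The localization head is then trained with
MSE at a constant learning rate of 1e-4 (default 400 epochs) with the
encoder frozen, using only patches whose predicted foreground is ≥15% of
the average vertebra volume — patches with little vertebra content carry no
location signal. The gate threshold is inclusive (≥).

## Center determination

Votes are placed at patch center + predicted offset and weighted by
predicted confidence; votes with confidence < 0.01 are dropped (near-zero
weights destabilize k-means), and votes inside a supplied pelvis mask are
excluded as outliers. For each k in [3, 19], weighted k-means (scikit-learn
backend; k-means++ seeding is weighted probabilistic farthest-point
seeding, fixed seed for determinism) produces candidate centers, z-sorted
with (z, y, x) tie-breaking. The clustering score is

    CS(k) = min_{i=1..k-2} G_i^dst(D_i) · G_{i+1}^dst(D_{i+1}) · G^diff(D_{i+1} − D_i)

with D_i the z-gap of the i-th neighboring pair from the bottom. The pair
Gaussians are per-level because inter-center distances drift from lumbar to
upper thoracic levels; the difference Gaussian is pooled because gap
*differences* are near-stationary. Fitting is per-pair maximum likelihood
(sample mean, biased sd) with an sd floor of 0.5 mm against degenerate
training data. Full normalized densities are used (a peak-normalized
variant is available behind a flag). k in [3, 19] admits up to 18 gaps but
only 17 pair Gaussians are fitted; the top-most extra gap reuses the last
Gaussian. The selected count is the argmax of CS (ties go to the smaller
k).

## Instance separation and recovery

The signed Euclidean distance map of the body label (negative inside,
computed with voxel spacing in mm) drives a seeded watershed: each selected
center is first shifted to the argmin of the distance map within a 5×5×5
window (iterated to a fixed point, max 10 iterations), snapped to the
nearest body voxel if still outside, and then used as a marker.  Flooding
is 6-connected in ascending distance order with scan-order tie-breaking.
Body components that contain no seed remain unlabeled *by design*: they are
exactly the candidates for the recovery step (a "nearest seed" assignment
would silently fuse missed vertebrae into their neighbors).

Boundary recovery grows each label by iterated one-voxel dilation
restricted to the body ∪ boundary foreground (max 5 rounds); contested
voxels go to the label with more face-adjacent claimants, ties to the lower
label.

Missed-vertebra recovery enumerates 26-connected unlabeled foreground
components (≥10 voxels, a noise floor) from largest to smallest; a
component is admitted as a new instance when inserting its center of mass
into the z-sorted center list does not decrease CS (CS(k+1) ≥ CS(k)), up to
the anatomical cap of 18 instances. The component center is its plain
center of mass, not an opened-body center, because a missed component may
be a fragment with no clean body. Finally, each instance keeps only its
largest connected component, internal cavities are filled via the
label-inversion trick, and instances are renumbered 1..k bottom to top
(anatomical naming such as L1/T12 is out of scope).

## Preprocessing and VOI

Scans are resampled to 0.977×0.977×2 mm (z-spacing 2 mm) — linear
interpolation for intensities (interpolation order is not canonical; linear
is assumed), nearest-neighbor for labels — then clipped to the [0.5, 99.5]
percentiles of a reference set and Z-score normalized with reference-set
statistics (percentiles are linearly interpolated between order statistics;
the sd is floored at 1e-6). Reference statistics live in a
`norm_stats.json` sidecar so test data are normalized with training-set
statistics.

The vertebra VOI is anchored on a user-supplied pelvis mask (its center of
mass defines the bottom center), an explicit bottom plane, or the scan
bottom as fallback; the pelvis CNN that produces such masks in a clinical
deployment is a separate prerequisite component and deliberately not part
of this package. Crop defaults are 128×256×256 voxels (z, y, x), with a
320×320 axial option for scans with larger spine curvature coverage; VOI
portions outside the scan are ignored.

## Synthetic phantom

The phantom generator is first-class, tested code and defines the study
conditions for the whole suite. Defaults: 3–18 vertebrae; ellipsoidal body
radii (12, 15, 15) mm (z, y, x); a 3-voxel-thick posterior box process of
length 15 mm (thick enough to make the opening-based center nontrivial,
thin enough to be removed by it); inter-center z-gaps drawn from N(30 mm,
2 mm) — lumbar-like spacing consistent with the distance-model training
sequences used in the tests; two-level intensities 40/400 HU with additive
N(0, 20 HU) noise on a 0.977×0.977×2 mm grid. Options: collapsed vertebrae
(z-extent reduced to 40% of nominal) and fused adjacent pairs (a bony
bridge making the union 26-connected). Identical specs produce
bit-identical output.

What the phantom does *not* emulate: cortical/trabecular texture, true
vertebral shape (facets, pedicles), spine curvature, metal artifacts, and
inter-subject anatomy variation. Passing phantom tests therefore
demonstrates the correctness of the machinery (encoding, localization
targets, clustering, watershed, recovery, metrics) and the trainability of
the network, not clinical-grade accuracy on real CT.

## Metrics

Per matched instance: Dice; signed (ds) and unsigned (du) mean surface
distance in mm, averaged over the *predicted* surface (directed — the
averaging surface is not canonical; directed-from-predicted matches the
stated sign rule), with predicted surface voxels inside the reference
counted negative; and the symmetric Hausdorff distance. Surfaces are
foreground voxels with a 6-neighbor background voxel (volume borders count
as background). Instance matching is greedy by descending voxel overlap,
one-to-one; F1 = 2TP/(2TP + FP + FN). Summaries report mean, population
sd, and median.

## Test scale and numerical choices

The suite validates against brute-force oracles on ≤32³ grids (set
arithmetic morphology, exhaustive distance searches, heap-based priority
flood), statistical oracles with closed-form standard errors, and
end-to-end phantom runs. The short training check uses a reduced
configuration (16×24×24 patches, 3 tiers, 4 base channels, 20 training
phantoms of 4 vertebrae, ~500 Adam steps) — sized so the whole suite runs
on one CPU in minutes; it verifies trainability and generalization to
held-out phantoms, nothing more. Vote simulations use 20 votes per center,
matching the ~8 patches × up to 3 vectors that cover an interior vertebra
at 50% patch overlap.

## Known limitations

* The numpy CNN trains orders of magnitude slower than a GPU framework;
  default (full-width) training configurations are provided but are
  CPU-days scale on real data volumes.
* Fused vertebrae from very low bone density are split only if the
  three-label prediction separates their bodies; the recovery step cannot
  fix a fused *body* prediction.
* Percentile clipping and Z-scoring assume a consistent HU calibration
  across the reference set; scanner-specific calibration and metal-artifact
  handling are out of scope.
* The localization-target mirror rule extrapolates absent neighbors
  linearly; at strong scoliotic curvature this position is biased, which
  only matters for confidence-0 training targets.
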