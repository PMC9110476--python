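# Methods

## Problem and model

`planepose` estimates the 6D pose — 3D translation plus 3D rotation — of a
2D grayscale slice relative to the centre of the 3D volume it was cut
from, using image content alone.  The motivating application is obstetric
ultrasound: predicting where an arbitrary scan plane sits relative to the
fetal brain centre enables plane-localisation feedback without tracking
hardware.  The estimator is a regression CNN: an image `I` maps to a
9-vector `θ = (t1, t2, t3, r1..r6)`.  The translation triple lives in
normalised volume coordinates (half-extent = 1, so every in-volume plane
centre has components in [−1, 1] regardless of physical brain size); the
six rotation parameters are the *continuous 6D rotation representation* —
the first two columns of the rotation matrix.  The forward pass
reconstructs a full rotation by Gram-Schmidt orthonormalisation:

    e1 = v1/‖v1‖,  u2 = v2 − (e1·v2) e1,  e2 = u2/‖u2‖,  R = (e1 e2 e1×e2)

Because any non-degenerate pair (v1, v2) lands on SO(3), the network head
is unconstrained and the map is continuous over all of SO(3) — the
property that makes this representation train reliably where Euler angles,
quaternions and axis-angle representations suffer discontinuities.

Training minimises

    L_total = L_rotation + λ · L_translation
    L_translation = (1/N) Σ ‖t′ − t‖₂     L_rotation = (1/N) Σ ‖R′ − R‖_F

i.e. batch means of plain (not squared) Euclidean/Frobenius norms, with
λ = 0.01 by default.  A `squared_norm` flag switches both terms to squared
norms, since the mean-of-norms form is sometimes written where a squared
error is meant; the plain form is the default.  The gradient is
back-propagated analytically through the Gram-Schmidt reconstruction
(normalisation, projection and cross-product each have closed-form
vector-Jacobian products).  Model selection keeps the epoch with the
lowest validation total loss on a seeded 20 % split of the training set.

Rotation error is reported as the geodesic distance on SO(3),
`arccos((trace(R″) − 1)/2)` with `R″ = R_predᵀ R_gt` and the trace clamped
to [−1, 1]; translation error as the Euclidean distance in mm after
denormalising against the evaluated volume's own extent (normalised
coordinates are volume-relative, so the per-volume extent is the only
consistent scale; the report records the extent used).

## Geometry conventions

* Volume physical origin at its centre; voxel `k` sits at
  `(k + 0.5)·spacing − extent/2` mm.  Intensities live in [0, 1].
* A slice plane lies in its local x–y plane, local z is the normal; pixel
  (row, col) maps to local (y, x) with the image centre at the origin.
  Plane-local points map into the volume as `p = R·p_local + t`.
* Euler angles (labels and reports only; all internal math uses matrices)
  follow the intrinsic Z-X-Y convention, right-handed, degrees, stored in
  [−180, 180).  The convention is a single named constant
  (`EULER_CONVENTION`) recorded in every dataset manifest, so datasets are
  self-describing and the convention is swappable.  At gimbal lock the
  third angle of the sequence is set to zero and its contribution folded
  into the first — deterministic and documented.
* Interpolation is trilinear with fill value 0 outside the volume
  (ultrasound background is black).  A point counts as inside when its
  continuous voxel index lies within the voxel-centre hull `[0, S−1]` per
  axis.  The slice sampler is hand-vectorised so that it is bit-identical
  to a naive per-pixel loop over the same arithmetic; a separate test
  cross-checks it against `scipy.ndimage.map_coordinates`.
* Degeneracy threshold in Gram-Schmidt: `‖v1‖` or `‖u2‖` below 1e−8
  raises (library path) rather than normalising noise; inside the network
  head the norms are clamped at 1e−8 instead, because a training step must
  stay differentiable everywhere the optimiser can reach.

## Synthetic phantom

The generator stands in for acquired 3D ultrasound of a mid-gestation
fetal-head phantom.  It is deliberately minimal: the downstream method
needs (a) pose identifiability — no rotational or mirror symmetry may
survive — and (b) speckle texture.  A volume contains a bright
ellipsoidal shell (skull) with unequal semi-axes, an echogenic midline
plane, two dark ventricle-like cavities of unequal size placed off every
symmetry axis, one bright focal structure in a single octant, a three-axis
linear intensity gradient with distinct weights (0.18/0.12/0.08 of the
tissue level per unit normalised coordinate — this breaks every 180°
flip at whole-volume scale, which the small interior structures alone do
only marginally), and smoothed multiplicative speckle (gamma noise with
mean 1 and standard deviation `speckle_strength`, default 0.25, smoothed
with a 0.8-voxel Gaussian to mimic correlated speckle grains).  A
pose-identifiability test checks that volume autocorrelation over the 24
cube-symmetry rotations peaks only at the identity.

What the phantom does **not** emulate: attenuation, shadowing,
refraction, fan-beam geometry, or anatomy beyond identifiability.
Passing tests therefore demonstrate that the pipeline recovers pose from
identifiable structure under speckle — not performance on clinical
scans.

The canonical "standard plane" of the phantom is a fixed, documented pose
(Euler (12°, 0°, 7°), translation (0, 0.04, 0.06) normalised) chosen to
pass through the ventricle-like cavities and midline, mimicking an
annotated transventricular plane.

## Dataset generation

Random-pose slices (subset `RP`): per-axis uniform translation in
±`trans_range` (default 0.5 normalised) and rotation composed from
per-axis uniform angles in ±`rot_range` (default 45°), rejection-resampled
until the slice overlaps the volume by at least `min_overlap` (default
0.75, estimated on a coarse 24² grid; `min_overlap = 0` disables
rejection).  The defaults are recorded in every manifest.  Near-SP slices
(subset `SP`): the i-th plane perturbs the annotated standard plane by
per-axis uniform translation/rotation whose intervals ramp linearly from
0.1 to 0.001 normalised units and from 7.9° to 1.9° across the sequence
(a linear schedule is the simplest monotone interpolation between the
documented coarse and fine interval endpoints).  Rotational perturbations
compose in the standard plane's own frame (`R = R_sp · ΔR`).

Slices are stored as 8-bit grayscale PNG; poses live only in the CSV
manifest (full float precision), whose header records the Euler
convention, field of view, resolution and seeds.  The default field of
view is the smallest volume extent, so an unrotated centred slice never
leaves the volume.

## Training recipes

Full-scale defaults follow the reference protocol for this task family:
ResNet-18 backbone, 128×128 inputs, 50 epochs, batch 100, Adam with
learning rate 1e−4 (β₁ = 0.9, β₂ = 0.999), λ = 0.01, 20 % validation
split.  No data augmentation is applied.  The network core is a compact
explicit-backpropagation CNN library (conv/maxpool/batch-norm/linear
layers, Adam) written in numpy: deterministic bit-for-bit from a seed,
single-threaded, with finite-difference tests for every layer.  The
18-layer residual backbone is assembled from those layers; no pretrained
weights ship with the package, so the `pretrained` toggle raises unless
weights are supplied externally.

The **desk-scale recipe** (`desk_scale_params()`) is what the acceptance
experiment and the worked example use: `smallconv` backbone, 64×64
inputs, 10 epochs, batch 15, Adam 3e−3 with half-cosine decay, λ = 0.01.
The `smallconv` architecture is four conv–batchnorm–relu–pool blocks
(24→192 channels) whose flattened output — flatten, not global pooling,
because translation regression needs the spatial layout — feeds two
*separate* fully connected branches: 384 hidden units for the six
rotation parameters, 256 for the translation triple.  Choices and why:

* split heads: with λ = 0.01 and mean-of-norms losses, the translation
  term contributes only ~1 % of the shared-trunk gradient (the gradient
  magnitude of a norm does not shrink as the error does, so the rotation
  term dominates throughout training).  A dedicated translation branch
  reads the shared conv features at a full adaptive learning rate, which
  in our experiments cut the median translation error by a third without
  touching λ or the loss;
* batch-norm and the 1e−3-scale learning rate are the standard recipe for
  training a small CNN from scratch (the 1e−4 default above belongs to a
  pretrained ResNet fine-tune);
* the half-cosine decay matters specifically for the mean-of-norms loss,
  whose constant-magnitude gradients make constant-rate Adam plateau at
  an oscillation floor;
* small batches buy more optimisation steps inside the fixed 10-epoch
  budget (batch 15 ≈ 2 700 updates);
* final layers start with shrunk weights, and the rotation output with an
  identity bias, so early training starts from the neutral pose instead
  of a random one.

## Desk-scale experiment

`planepose.experiments.run_parameter_recovery` builds a 64³ phantom
(1 mm voxels), samples 4000 training and 500 test random-pose slices plus
250 near-SP test slices at 64×64, trains the desk-scale recipe, and
compares median held-out errors against the constant mean-pose predictor
(mean translation, chordal-mean rotation of the training labels).  These
problem sizes keep the full experiment in the ten-minute range on one CPU
while leaving the learning problem non-trivial.  The improvement factor
on median geodesic error and the median normalised translation error are
the experiment's headline numbers; the near-SP subset's medians are
reported alongside as a directional (not gated) comparison, since at this
scale the margin between subsets is small and seed-noisy.

## Numerical choices and edge cases

* `arccos` inputs are clamped to [−1, 1]; note geodesic distances below
  ~1e−5 degrees are dominated by `arccos` rounding, so "zero" distance
  tests use that tolerance.
* Even-length medians are the midpoint of the central pair (numpy
  convention).
* Translation/rotation loss gradients guard the norm denominator at
  1e−8 (the gradient of ‖·‖ is undefined at 0).
* Volume loading rescales intensities to [0, 1] only when the data lie
  outside that range, so already-normalised volumes round-trip exactly.
* Non-isotropic voxel spacing is accepted with a logged warning.
* Empty evaluation subsets are omitted from the report with a warning
  rather than crashing.
* Rejection sampling raises after 1000 consecutive failures with advice
  to widen `min_overlap` or narrow the ranges.

## Known limitations

* The phantom is an idealised stand-in; results do not transfer to real
  fetal anatomy, inter-subject variation, or probe-dependent artefacts.
* The full-scale protocol (ResNet-18, 128², 75k images, 50 epochs) is
  implemented but not exercised by the test suite, which runs the
  desk-scale recipe; the numpy core is correct but not fast enough for
  the full-scale configuration in reasonable CPU time.
* Curvilinear/fan-beam geometry and volume-to-volume registration are out
  of scope; volumes are assumed pre-aligned to a common anatomical frame.
* The Euler convention of external annotations must match the package's
  (`ZXY` intrinsic); the annotation loader rejects anything else rather
  than guessing.
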