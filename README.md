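# planepose

Estimate the 6D pose — 3D translation and 3D rotation — of a 2D
grayscale slice relative to the centre of the 3D volume it was cut from,
using image content alone.  The target application is obstetric
ultrasound training and navigation: given an arbitrary scan plane of the
fetal brain, predict where that plane sits relative to the brain centre
without any tracking hardware, so a trainee can be guided towards the
guideline-defined standard planes.  The package is aimed at researchers in
medical image analysis who want a fully self-contained, CPU-reproducible
version of this pipeline: it ships a procedural ultrasound-like phantom
generator, so every experiment builds from a seed with no data download.

## Method

A regression CNN maps a slice image `I` to nine parameters
`θ = (t1, t2, t3, r1, …, r6)`.  The translation `t` is expressed in
normalised volume coordinates (half-extent = 1).  The rotation uses the
continuous 6D representation — the first two columns of the rotation
matrix — and the forward pass reconstructs a proper rotation by
Gram-Schmidt orthonormalisation:

    e1 = v1/‖v1‖,  u2 = v2 − (e1·v2)e1,  e2 = u2/‖u2‖,  R′ = (e1 e2 e1×e2)

so every network output is a valid pose, and the representation is
continuous over all of SO(3) (Euler angles, quaternions and axis-angle
are not, which makes them unreliable regression targets).  Training
minimises

    L_total = (1/N) Σ ‖R′ − R‖_F  +  λ · (1/N) Σ ‖t′ − t‖₂ ,   λ = 0.01

with gradients propagated analytically through the Gram-Schmidt map.
Errors are reported the way this literature reports them: translation as
Euclidean distance in mm, rotation as the geodesic distance
`arccos((trace(R″) − 1)/2)`, `R″ = R′ᵀ R`, in degrees, aggregated as
median/min/max over the random-pose (`RP`) and near-standard-plane
(`SP`) test subsets.

See `docs/methods.md` for conventions, the phantom design, and the
training recipes.

## Worked example

The whole pipeline from a shell (a few minutes on one CPU):

```sh
planepose phantom --out vol.nii.gz --size 48 --seed 5
planepose dataset --volume vol.nii.gz --sp vol.nii.gz.sp.json \
    --out-dir data --n-random 400 --n-near-sp 100 --resolution 32 --seed 6
planepose train --dataset-dir data --out ckpt.npz \
    --backbone smallconv --image-size 32 --epochs 10 \
    --batch-size 25 --learning-rate 0.002 --seed 7
planepose eval --checkpoint ckpt.npz --dataset-dir data \
    --volume vol.nii.gz --out-dir report
```

The `eval` step prints a per-subset summary table (and writes
`report/eval_summary.json` plus the per-plane `report/eval_records.csv`):

```
Subset       n        Trans med/min/max [mm]       Rot med/min/max [deg]
RP         400     5.550/  0.351/   17.915    27.522/  2.064/ 75.340
SP         100     1.041/  0.306/    3.226     8.663/  2.461/ 14.961
```

Translation errors are in mm inside the 48 mm phantom; rotation errors
are geodesic degrees.  Random planes (`RP`) span the whole ±45°/±0.5
sampling range, while `SP` planes cluster tightly around the annotated
standard plane, which is why their errors are far smaller.  This
miniature demo evaluates the model on its own 500-image training set —
a consistency check, not a benchmark; the held-out desk-scale experiment
below is the meaningful one.

The same pipeline is available as a library of scikit-learn-style
estimators:

```python
import numpy as np, planepose as pp

vol = pp.generate_phantom_volume(pp.PhantomParams.for_shape((64,)*3, 1.0, seed=1))
cfg = pp.PoseSamplerConfig(seed=2)
rng = np.random.default_rng(2)
poses = [pp.sample_random_pose(rng, cfg, vol) for _ in range(1000)]
X = pp.render_slices(vol, poses, float(vol.extent.min()), 64)
y = np.stack([p.as_target() for p in poses])

est = pp.PlanePoseRegressor(seed=3, **pp.desk_scale_params())
est.fit(X, y)
pose = est.predict_pose(X[0])          # -> planepose.Pose
```

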