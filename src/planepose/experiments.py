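"""Self-contained desk-scale experiment: phantom parameter recovery.

Builds a synthetic phantom, samples labelled slices, trains the pose
regressor with the desk-scale recipe, and measures held-out pose-recovery
errors against the constant mean-pose baseline — the package's scaled-down
analogue of training and testing on acquired phantom volumes.  Problem
sizes default to a 64^3 phantom with 4000 training and 500 random-pose
test slices at 64x64 pixels, plus a near-standard-plane test subset, so
the whole run fits in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from .dataset import PoseSamplerConfig, render_slices, sample_near_sp_poses, sample_random_pose
from .phantom import PhantomParams, canonical_standard_plane, generate_phantom_volume
from .regressor import PlanePoseRegressor, desk_scale_params, mean_pose_baseline
from .rotations import Pose, geodesic_distance_deg
from .volume import default_field_of_view

__all__ = ["run_parameter_recovery"]


def _pose_errors(pred_thetas, gt_poses, extent):
    rot, trans, trans_mm = [], [], []
    for theta, gt in zip(pred_thetas, gt_poses):
        pred = Pose.from_target(theta)
        rot.append(geodesic_distance_deg(pred.rotation, gt.rotation))
        d = pred.translation - gt.translation
        trans.append(float(np.linalg.norm(d)))
        trans_mm.append(float(np.linalg.norm(d * extent / 2.0)))
    return np.array(rot), np.array(trans), np.array(trans_mm)


def run_parameter_recovery(
    seed: int = 0,
    n_train: int = 4000,
    n_test_rp: int = 500,
    n_test_sp: int = 250,
    grid: int = 64,
    resolution: int = 64,
    verbose: int = 0,
) -> dict:
    """Train on random-pose slices of a synthetic phantom and measure
    held-out recovery errors.

    Returns a dict with per-subset median errors (geodesic degrees,
    normalised translation, translation mm), the constant mean-pose
    baseline on the random-pose subset, and the improvement factor of the
    model over that baseline on median geodesic error.
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(6) % (2 ** 31)
    params = PhantomParams.for_shape((grid,) * 3, 1.0, seed=int(seeds[0]))
    volume = generate_phantom_volume(params)
    fov = default_field_of_view(volume)

    config = PoseSamplerConfig(seed=int(seeds[1]))
    rng_train = np.random.default_rng(int(seeds[1]))
    rng_test = np.random.default_rng(int(seeds[2]))
    rng_sp = np.random.default_rng(int(seeds[3]))

    train_poses = [sample_random_pose(rng_train, config, volume, fov)
                   for _ in range(n_train)]
    test_poses = [sample_random_pose(rng_test, config, volume, fov)
                  for _ in range(n_test_rp)]
    sp = canonical_standard_plane()
    sp_config = PoseSamplerConfig(seed=int(seeds[3]), n_near_sp=n_test_sp)
    sp_poses = sample_near_sp_poses(rng_sp, sp, sp_config, volume, fov)

    X_train = render_slices(volume, train_poses, fov, resolution)
    y_train = np.stack([p.as_target() for p in train_poses])
    X_rp = render_slices(volume, test_poses, fov, resolution)
    X_sp = render_slices(volume, sp_poses, fov, resolution)

    est = PlanePoseRegressor(seed=int(seeds[4]), verbose=verbose,
                             **desk_scale_params())
    est.fit(X_train, y_train)

    extent = volume.extent
    rot_rp, trans_rp, mm_rp = _pose_errors(est.predict(X_rp), test_poses, extent)
    rot_sp, trans_sp, mm_sp = _pose_errors(est.predict(X_sp), sp_poses, extent)

    baseline = mean_pose_baseline(y_train)
    base_rot = np.array([geodesic_distance_deg(baseline.rotation, p.rotation)
                         for p in test_poses])
    base_trans = np.array([np.linalg.norm(baseline.translation - p.translation)
                           for p in test_poses])

    return {
        "estimator": est,
        "n_train": n_train,
        "n_test_rp": n_test_rp,
        "n_test_sp": n_test_sp,
        "median_rot_deg_rp": float(np.median(rot_rp)),
        "median_trans_norm_rp": float(np.median(trans_rp)),
        "median_trans_mm_rp": float(np.median(mm_rp)),
        "median_rot_deg_sp": float(np.median(rot_sp)),
        "median_trans_norm_sp": float(np.median(trans_sp)),
        "median_trans_mm_sp": float(np.median(mm_sp)),
        "baseline_median_rot_deg_rp": float(np.median(base_rot)),
        "baseline_median_trans_norm_rp": float(np.median(base_trans)),
        "rot_improvement_factor": float(np.median(base_rot) / np.median(rot_rp)),
    }
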