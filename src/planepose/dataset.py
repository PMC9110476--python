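"""Pose sampling and dataset construction.

Two pose populations are produced, mirroring how training data is built
for plane-pose regression: planes at random poses (subset ``RP``) drawn
uniformly within fixed translation/rotation ranges, and planes densely
sampled around an annotated standard plane (subset ``SP``) whose
perturbation intervals ramp linearly from coarse to fine across the
sequence (defaults 0.1 -> 0.001 normalised units for translation and
7.9 deg -> 1.9 deg for rotation).  Poses with poor overlap with the volume
are rejection-resampled.

Datasets are written as 8-bit PNG slices plus a CSV manifest whose header
records the geometry conventions, so every dataset is self-describing.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import SPAnnotation
from .rotations import (
    EULER_CONVENTION,
    Pose,
    euler_to_rotation,
    random_rotation_in_range,
)
from .volume import (
    SlicePlaneSpec,
    Volume,
    default_field_of_view,
    extract_slice,
    overlap_fraction,
    save_slice_png,
)

__all__ = [
    "PoseSamplerConfig",
    "DatasetManifest",
    "sample_random_pose",
    "sample_near_sp_poses",
    "build_dataset",
    "render_slices",
    "read_manifest",
    "write_manifest",
]

MANIFEST_COLUMNS = [
    "image_path", "volume_id", "subset",
    "t_x", "t_y", "t_z", "a_x", "a_y", "a_z", "overlap",
]

_MAX_REJECTIONS = 1000

#: Resolution at which overlap is estimated during rejection sampling;
#: coarse on purpose (overlap is a fraction, not an image).
_OVERLAP_RES = 24


@dataclass
class PoseSamplerConfig:
    """Sampling ranges and counts for dataset generation.

    Translation quantities are in normalised units (volume half-extent = 1),
    rotations in degrees.  ``min_overlap = 0`` disables rejection.
    """

    n_random: int = 1000
    n_near_sp: int = 100
    trans_range: float = 0.5
    rot_range: float = 45.0
    sp_trans_interval_max: float = 0.1
    sp_trans_interval_min: float = 0.001
    sp_rot_interval_max: float = 7.9
    sp_rot_interval_min: float = 1.9
    min_overlap: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_random < 0 or self.n_near_sp < 0:
            raise ValueError("pose counts must be non-negative")
        if not (0.0 <= self.min_overlap <= 1.0):
            raise ValueError(f"min_overlap must be in [0, 1], got {self.min_overlap}")
        if self.sp_trans_interval_max < self.sp_trans_interval_min:
            raise ValueError("sp_trans_interval_max must be >= sp_trans_interval_min")
        if self.sp_rot_interval_max < self.sp_rot_interval_min:
            raise ValueError("sp_rot_interval_max must be >= sp_rot_interval_min")


def _overlap_ok(pose: Pose, volume: Volume, config: PoseSamplerConfig,
                field_of_view: float | None) -> bool:
    if config.min_overlap <= 0.0:
        return True
    fov = field_of_view if field_of_view is not None else default_field_of_view(volume)
    spec = SlicePlaneSpec(pose=pose, field_of_view=fov, resolution=_OVERLAP_RES)
    return overlap_fraction(volume, spec) >= config.min_overlap


def sample_random_pose(
    rng: np.random.Generator,
    config: PoseSamplerConfig,
    volume: Volume,
    field_of_view: float | None = None,
) -> Pose:
    """One pose with per-axis uniform translation in ``[-trans_range,
    +trans_range]`` and rotation from per-axis uniform angles in
    ``[-rot_range, +rot_range]``, rejection-resampled until the slice
    overlaps the volume by at least ``min_overlap``.
    """
    for _ in range(_MAX_REJECTIONS):
        t = rng.uniform(-config.trans_range, config.trans_range, size=3)
        R = random_rotation_in_range(rng, config.rot_range)
        pose = Pose(R, t)
        if _overlap_ok(pose, volume, config, field_of_view):
            return pose
    raise RuntimeError(
        f"{_MAX_REJECTIONS} consecutive pose rejections; widen min_overlap "
        f"(currently {config.min_overlap}) or narrow the sampling ranges"
    )


def sample_near_sp_poses(
    rng: np.random.Generator,
    sp: SPAnnotation,
    config: PoseSamplerConfig,
    volume: Volume,
    field_of_view: float | None = None,
) -> list[Pose]:
    """``n_near_sp`` poses perturbing the standard plane.

    The i-th pose perturbs the SP pose by per-axis uniform translation in
    ``+-trans_interval_i`` and per-axis uniform rotation angles in
    ``+-rot_interval_i``; both intervals ramp linearly from their max to
    their min across the sequence.  The rotational perturbation is applied
    in the standard plane's own frame (``R = R_sp @ R_delta``).
    """
    n = config.n_near_sp
    if n == 0:
        return []
    ramp = np.linspace(1.0, 0.0, n) if n > 1 else np.array([1.0])
    t_int = config.sp_trans_interval_min + ramp * (
        config.sp_trans_interval_max - config.sp_trans_interval_min)
    r_int = config.sp_rot_interval_min + ramp * (
        config.sp_rot_interval_max - config.sp_rot_interval_min)
    poses: list[Pose] = []
    for ti, ri in zip(t_int, r_int):
        for _ in range(_MAX_REJECTIONS):
            dt = rng.uniform(-ti, ti, size=3)
            dR = random_rotation_in_range(rng, ri)
            pose = Pose(sp.pose.rotation @ dR, sp.pose.translation + dt)
            if _overlap_ok(pose, volume, config, field_of_view):
                poses.append(pose)
                break
        else:
            raise RuntimeError(
                f"{_MAX_REJECTIONS} consecutive pose rejections near the "
                "standard plane; widen min_overlap or narrow the intervals"
            )
    return poses


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass
class DatasetManifest:
    """Table of slice rows plus self-describing geometry metadata.

    ``meta`` must carry at least ``euler_convention``, ``field_of_view``
    and ``resolution``; sampler seeds and ranges are recorded for audit.
    """

    rows: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        for key in ("euler_convention", "field_of_view", "resolution"):
            if key not in self.meta:
                raise ValueError(f"manifest metadata missing {key!r}")
        bad = set(self.rows["subset"]) - {"RP", "SP"}
        if bad:
            idx = self.rows.index[~self.rows["subset"].isin(["RP", "SP"])][0]
            raise ValueError(f"unknown subset tag {bad} at row {idx}")
        num = self.rows[["t_x", "t_y", "t_z", "a_x", "a_y", "a_z", "overlap"]]
        if not np.all(np.isfinite(num.to_numpy(dtype=float))):
            raise ValueError("manifest contains non-finite pose values")

    def pose(self, i: int) -> Pose:
        row = self.rows.iloc[i]
        R = euler_to_rotation(
            np.array([row.a_x, row.a_y, row.a_z]),
            convention=self.meta["euler_convention"],
        )
        return Pose(R, np.array([row.t_x, row.t_y, row.t_z]))

    def poses(self) -> list[Pose]:
        return [self.pose(i) for i in range(len(self.rows))]

    def fingerprint(self) -> str:
        buf = io.StringIO()
        self.rows.to_csv(buf, index=False)
        return hashlib.sha256(buf.getvalue().encode()).hexdigest()[:16]


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """CSV with ``# key=value`` metadata header lines; numeric fields keep
    full float precision (``repr`` round-trip)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for key in sorted(manifest.meta):
            fh.write(f"# {key}={manifest.meta[key]}\n")
        manifest.rows.to_csv(fh, index=False)


def read_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    meta: dict = {}
    header_lines = 0
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    for key in ("field_of_view",):
        if key in meta:
            meta[key] = float(meta[key])
    for key in ("resolution", "seed", "n_random", "n_near_sp"):
        if key in meta:
            meta[key] = int(float(meta[key]))
    rows = pd.read_csv(path, skiprows=header_lines)
    return DatasetManifest(rows=rows, meta=meta)


# ---------------------------------------------------------------------------
# Dataset building
# ---------------------------------------------------------------------------

def render_slices(
    volume: Volume,
    poses: list[Pose],
    field_of_view: float,
    resolution: int,
) -> np.ndarray:
    """Stack of slice images (N, res, res) for a list of poses."""
    out = np.empty((len(poses), resolution, resolution), dtype=np.float32)
    for i, pose in enumerate(poses):
        spec = SlicePlaneSpec(pose=pose, field_of_view=field_of_view,
                              resolution=resolution)
        out[i] = extract_slice(volume, spec).pixels
    return out


def build_dataset(
    volume: Volume,
    sp: SPAnnotation | None,
    config: PoseSamplerConfig,
    out_dir: str | Path,
    field_of_view: float | None = None,
    resolution: int = 128,
    volume_id: str = "phantom",
) -> DatasetManifest:
    """Sample poses, write PNG slices and a manifest under ``out_dir``.

    Produces exactly ``n_random`` RP rows and ``n_near_sp`` SP rows; a
    standard-plane annotation is required iff ``n_near_sp > 0``.
    """
    if config.n_near_sp > 0 and sp is None:
        raise ValueError("n_near_sp > 0 requires a standard-plane annotation")
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    fov = field_of_view if field_of_view is not None else default_field_of_view(volume)

    rng = np.random.default_rng(config.seed)
    poses = [(sample_random_pose(rng, config, volume, fov), "RP")
             for _ in range(config.n_random)]
    if config.n_near_sp > 0:
        assert sp is not None
        poses += [(p, "SP") for p in
                  sample_near_sp_poses(rng, sp, config, volume, fov)]

    records = []
    for i, (pose, subset) in enumerate(poses):
        spec = SlicePlaneSpec(pose=pose, field_of_view=fov, resolution=resolution)
        sl = extract_slice(volume, spec)
        rel = f"images/{subset.lower()}_{i:06d}.png"
        save_slice_png(sl.pixels, out_dir / rel)
        ax, ay, az = pose.euler()
        records.append({
            "image_path": rel, "volume_id": volume_id, "subset": subset,
            "t_x": pose.translation[0], "t_y": pose.translation[1],
            "t_z": pose.translation[2],
            "a_x": ax, "a_y": ay, "a_z": az,
            "overlap": sl.overlap,
        })

    manifest = DatasetManifest(
        rows=pd.DataFrame.from_records(records, columns=MANIFEST_COLUMNS),
        meta={
            "euler_convention": EULER_CONVENTION,
            "field_of_view": fov,
            "resolution": resolution,
            "seed": config.seed,
            "n_random": config.n_random,
            "n_near_sp": config.n_near_sp,
            "trans_range": config.trans_range,
            "rot_range": config.rot_range,
            "min_overlap": config.min_overlap,
            "volume_id": volume_id,
        },
    )
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
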