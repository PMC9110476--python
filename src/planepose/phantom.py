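"""Procedural brain-like ultrasound phantom volumes.

The generator stands in for acquired 3D ultrasound of a mid-gestation
fetal-head phantom.  Realism is deliberately minimal: the downstream pose
regressor only needs (a) a structure whose appearance identifies the
slicing pose uniquely — so every rotational and mirror symmetry must be
broken — and (b) ultrasound-like multiplicative speckle texture.  The
volume therefore contains a bright ellipsoidal shell (skull), an echogenic
midline, a pair of dark ventricle-like cavities of unequal size placed
off-axis, one bright focal structure, an intensity gradient, and smoothed
multiplicative speckle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .rotations import EULER_CONVENTION, Pose, euler_to_rotation
from .volume import Volume

__all__ = [
    "PhantomParams",
    "SPAnnotation",
    "generate_phantom_volume",
    "canonical_standard_plane",
    "save_sp_annotation",
    "load_sp_annotation",
]


@dataclass
class PhantomParams:
    """Parameters of the procedural phantom.

    ``skull_radii`` are the outer semi-axes of the skull ellipsoid in mm
    and must fit inside the volume extent.  ``structure_count`` is the
    number of internal structures (the four canonical ones plus seeded
    random blobs beyond that).  ``speckle_strength`` in [0, 1] scales the
    standard deviation of the multiplicative speckle field.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: float = 1.0
    skull_radii: tuple[float, float, float] = (39.0, 34.0, 28.0)
    structure_count: int = 4
    speckle_strength: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.speckle_strength <= 1.0):
            raise ValueError(f"speckle_strength must be in [0, 1], got {self.speckle_strength}")
        if self.structure_count < 3:
            raise ValueError("structure_count must be >= 3 to break all symmetries")
        extent = np.asarray(self.shape) * self.spacing
        if np.any(2.0 * np.asarray(self.skull_radii) >= extent):
            raise ValueError(
                f"skull radii {self.skull_radii} do not fit inside extent {tuple(extent)} mm"
            )

    @classmethod
    def for_shape(cls, shape: tuple[int, int, int], spacing: float = 1.0, **kwargs) -> "PhantomParams":
        """Defaults with skull radii scaled to the given grid."""
        half = np.asarray(shape) * spacing / 2.0
        radii = tuple(np.round(half * np.array([0.82, 0.71, 0.59]), 1))
        return cls(shape=tuple(shape), spacing=spacing, skull_radii=radii, **kwargs)


def _ellipsoid_mask(x, y, z, centre, radii) -> np.ndarray:
    cx, cy, cz = centre
    rx, ry, rz = radii
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def generate_phantom_volume(params: PhantomParams) -> Volume:
    """Deterministic brain-like phantom volume, intensities in [0, 1]."""
    rng = np.random.default_rng(params.seed)
    shape = np.asarray(params.shape)
    spacing = params.spacing
    extent = shape * spacing
    axes = [
        (np.arange(n) + 0.5) * spacing - e / 2.0 for n, e in zip(shape, extent)
    ]
    x, y, z = np.meshgrid(*axes, indexing="ij")

    rx, ry, rz = params.skull_radii
    rho = np.sqrt((x / rx) ** 2 + (y / ry) ** 2 + (z / rz) ** 2)

    vol = np.full(shape, 0.03)                       # anechoic background
    inside = rho < 0.92
    # tissue with a three-axis intensity gradient: distinct weights per axis
    # break every 180-degree flip at whole-volume scale
    vol[inside] = (0.38 + 0.18 * (x[inside] / rx)
                   + 0.12 * (y[inside] / ry) + 0.08 * (z[inside] / rz))
    vol[(rho >= 0.92) & (rho <= 1.0)] = 0.90         # skull shell

    # echogenic midline (sagittal plane y = 0), confined to the interior
    midline = (np.abs(y) < 1.5 * spacing) & (rho < 0.85)
    vol[midline] = 0.68

    # dark ventricle-like cavities of unequal size, placed to break mirror
    # symmetry about the midline and about every coordinate plane
    v1 = _ellipsoid_mask(x, y, z, (-0.30 * rx, 0.18 * ry, 0.10 * rz),
                         (0.30 * rx, 0.14 * ry, 0.14 * rz))
    v2 = _ellipsoid_mask(x, y, z, (0.26 * rx, -0.12 * ry, 0.04 * rz),
                         (0.20 * rx, 0.09 * ry, 0.09 * rz))
    vol[v1 | v2] = 0.08

    # one bright focal structure in a single octant
    focal = _ellipsoid_mask(x, y, z, (0.15 * rx, 0.38 * ry, -0.32 * rz),
                            (0.12 * rx, 0.12 * ry, 0.12 * rz))
    vol[focal] = 0.95

    # extra seeded blobs beyond the four canonical structures
    for _ in range(max(0, params.structure_count - 4)):
        centre = rng.uniform(-0.4, 0.4, size=3) * np.array([rx, ry, rz])
        radius = rng.uniform(0.05, 0.10) * min(rx, ry, rz)
        value = rng.choice([0.12, 0.80])
        vol[_ellipsoid_mask(x, y, z, centre, (radius,) * 3)] = value

    if params.speckle_strength > 0:
        s = params.speckle_strength
        k = 1.0 / (s * s)  # gamma with mean 1, variance s^2
        noise = rng.gamma(k, 1.0 / k, size=tuple(shape))
        noise = gaussian_filter(noise, sigma=0.8)
        vol = vol * noise

    return Volume(grid=np.clip(vol, 0.0, 1.0).astype(np.float32),
                  spacing=np.full(3, spacing))


# ---------------------------------------------------------------------------
# Standard-plane annotation
# ---------------------------------------------------------------------------

#: Euler angles (deg) and normalised translation of the phantom's canonical
#: "standard plane": a slightly tilted axial-style plane passing through the
#: ventricle-like cavities and the midline echo.
CANONICAL_SP_EULER = (12.0, 0.0, 7.0)
CANONICAL_SP_TRANSLATION = (0.0, 0.04, 0.06)


@dataclass
class SPAnnotation:
    """A standard-plane pose annotation for one volume."""

    pose: Pose
    volume_id: str = "phantom"
    annotator: str = "synthetic"


def canonical_standard_plane(volume_id: str = "phantom") -> SPAnnotation:
    """The phantom's fixed, documented standard-plane annotation."""
    pose = Pose(
        euler_to_rotation(np.array(CANONICAL_SP_EULER)),
        np.array(CANONICAL_SP_TRANSLATION),
    )
    return SPAnnotation(pose=pose, volume_id=volume_id, annotator="synthetic")


def save_sp_annotation(sp: SPAnnotation, path: str | Path) -> None:
    payload = {
        "volume_id": sp.volume_id,
        "annotator": sp.annotator,
        "t": [float(v) for v in sp.pose.translation],
        "euler_deg": [float(v) for v in sp.pose.euler()],
        "convention": EULER_CONVENTION,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_sp_annotation(path: str | Path) -> SPAnnotation:
    payload = json.loads(Path(path).read_text())
    for key in ("volume_id", "t", "euler_deg", "convention"):
        if key not in payload:
            raise ValueError(f"standard-plane annotation missing field {key!r}")
    if payload["convention"] != EULER_CONVENTION:
        raise ValueError(
            f"annotation uses convention {payload['convention']!r}; "
            f"this package stores {EULER_CONVENTION!r}"
        )
    pose = Pose(euler_to_rotation(np.asarray(payload["euler_deg"], float)),
                np.asarray(payload["t"], float))
    return SPAnnotation(pose=pose, volume_id=payload["volume_id"],
                        annotator=payload.get("annotator", ""))
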