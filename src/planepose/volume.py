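"""Volume I/O and oblique-plane slice extraction.

Geometry conventions (used everywhere in the package):

* The volume's physical origin sits at its centre; the mm position of voxel
  index ``k`` along an axis is ``(k + 0.5) * spacing - extent / 2``.
* A slice lives in its local x-y plane with local z as the plane normal.
  Pixel ``(row, col)`` maps to local ``(y, x)`` with the image centre at
  the local origin.
* A pose maps plane-local points into the volume frame as
  ``p_volume = R @ p_local + t`` where ``t`` is the plane-centre offset
  (stored normalised, converted to mm against the volume half-extent).
* Sampling is trilinear; points outside the voxel-centre hull get fill
  value 0 (ultrasound background is black).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .rotations import Pose

__all__ = [
    "Volume",
    "SlicePlaneSpec",
    "SliceImage",
    "load_volume",
    "save_volume",
    "extract_slice",
    "overlap_fraction",
    "normalize_translation",
    "denormalize_translation",
    "save_slice_png",
    "load_slice_png",
]

logger = logging.getLogger(__name__)


@dataclass
class Volume:
    """3D intensity grid with physical voxel spacing.

    ``grid`` holds intensities in [0, 1]; ``spacing`` is the per-axis voxel
    size in mm.  ``extent`` (mm) is ``shape * spacing``.
    """

    grid: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"volume grid must be 3-D, got {self.grid.ndim}-D data")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if not np.allclose(self.spacing, self.spacing[0]):
            logger.warning("non-isotropic voxel spacing %s", self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def extent(self) -> np.ndarray:
        """Physical size in mm per axis."""
        return np.asarray(self.grid.shape) * self.spacing


@dataclass
class SlicePlaneSpec:
    """A slicing-plane request: pose + physical field of view + resolution."""

    pose: Pose
    field_of_view: float
    resolution: int

    def __post_init__(self) -> None:
        if self.field_of_view <= 0:
            raise ValueError(f"field_of_view must be positive, got {self.field_of_view}")
        if self.resolution < 2:
            raise ValueError(f"resolution must be >= 2, got {self.resolution}")


@dataclass
class SliceImage:
    """Extracted 2D slice with its pose label and bookkeeping."""

    pixels: np.ndarray
    label: Pose
    subset: str | None = None
    overlap: float = 1.0


def default_field_of_view(volume: Volume) -> float:
    """Smallest volume extent: an unrotated centred slice never leaves it."""
    return float(np.min(volume.extent))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_volume(path: str | Path) -> Volume:
    """Load a 3D NIfTI volume; spacing from the header, intensities in [0, 1].

    Intensities already inside [0, 1] pass through unchanged; anything else
    is min-max rescaled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume data, file has {data.ndim} dimensions")
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if np.any(zooms <= 0):
        raise ValueError(f"non-positive voxel spacing in header: {zooms}")
    lo, hi = float(data.min()), float(data.max())
    if lo < 0.0 or hi > 1.0:
        data = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
    return Volume(grid=data, spacing=zooms)


def save_volume(volume: Volume, path: str | Path) -> None:
    """Write a Volume as NIfTI with its spacing in the header."""
    path = Path(path)
    affine = np.diag([*volume.spacing, 1.0])
    affine[:3, 3] = -volume.extent / 2.0
    img = nib.Nifti1Image(np.asarray(volume.grid, dtype=np.float32), affine)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Coordinate maps
# ---------------------------------------------------------------------------

def normalize_translation(t_mm: np.ndarray, extent: np.ndarray) -> np.ndarray:
    """mm offset -> normalised units: ``t_norm = t_mm / (extent / 2)``."""
    extent = np.asarray(extent, dtype=float).reshape(3)
    if np.any(extent <= 0):
        raise ValueError(f"extent must be positive, got {extent}")
    return np.asarray(t_mm, dtype=float).reshape(3) / (extent / 2.0)


def denormalize_translation(t_norm: np.ndarray, extent: np.ndarray) -> np.ndarray:
    """Normalised units -> mm; inverse of :func:`normalize_translation`."""
    extent = np.asarray(extent, dtype=float).reshape(3)
    if np.any(extent <= 0):
        raise ValueError(f"extent must be positive, got {extent}")
    return np.asarray(t_norm, dtype=float).reshape(3) * (extent / 2.0)


def _plane_points_mm(spec: SlicePlaneSpec) -> np.ndarray:
    """Plane-local mm coordinates of all pixel centres, shape (res*res, 3)."""
    n = spec.resolution
    pitch = spec.field_of_view / n
    coords = (np.arange(n) + 0.5) * pitch - spec.field_of_view / 2.0
    xx, yy = np.meshgrid(coords, coords)  # row -> y, col -> x
    pts = np.stack([xx.ravel(), yy.ravel(), np.zeros(n * n)], axis=1)
    return pts


def _volume_points_mm(spec: SlicePlaneSpec, extent: np.ndarray) -> np.ndarray:
    # composed as explicit column combinations (not a matmul) so the result
    # is bit-identical to a per-pixel loop over the same formula
    t_mm = denormalize_translation(spec.pose.translation, extent)
    local = _plane_points_mm(spec)
    R = spec.pose.rotation
    return (local[:, 0:1] * R[:, 0] + local[:, 1:2] * R[:, 1]) + t_mm


def trilinear_sample(grid: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear interpolation at continuous voxel indices.

    ``idx`` has shape (P, 3).  A point is in bounds when every coordinate
    lies in ``[0, shape-1]`` (the voxel-centre hull); out-of-bounds points
    return 0.  Returns ``(values, inside_mask)``.
    """
    shape = np.asarray(grid.shape)
    inside = np.all((idx >= 0.0) & (idx <= shape - 1.0), axis=1)
    base = np.floor(idx).astype(np.int64)
    base = np.clip(base, 0, shape - 2)
    frac = idx - base
    b0, b1, b2 = base[:, 0], base[:, 1], base[:, 2]
    fx, fy, fz = frac[:, 0], frac[:, 1], frac[:, 2]
    g = grid
    c000 = g[b0, b1, b2]
    c100 = g[b0 + 1, b1, b2]
    c010 = g[b0, b1 + 1, b2]
    c110 = g[b0 + 1, b1 + 1, b2]
    c001 = g[b0, b1, b2 + 1]
    c101 = g[b0 + 1, b1, b2 + 1]
    c011 = g[b0, b1 + 1, b2 + 1]
    c111 = g[b0 + 1, b1 + 1, b2 + 1]
    c00 = c000 * (1.0 - fx) + c100 * fx
    c10 = c010 * (1.0 - fx) + c110 * fx
    c01 = c001 * (1.0 - fx) + c101 * fx
    c11 = c011 * (1.0 - fx) + c111 * fx
    c0 = c00 * (1.0 - fy) + c10 * fy
    c1 = c01 * (1.0 - fy) + c11 * fy
    values = c0 * (1.0 - fz) + c1 * fz
    values = np.where(inside, values, 0.0)
    return values, inside


def mm_to_index(points_mm: np.ndarray, volume: Volume) -> np.ndarray:
    """Centre-origin mm coordinates -> continuous voxel indices."""
    return (points_mm + volume.extent / 2.0) / volume.spacing - 0.5


def extract_slice(volume: Volume, spec: SlicePlaneSpec) -> SliceImage:
    """Resample a 2D slice of ``volume`` at the pose in ``spec``.

    Pixels outside the volume are filled with 0; ``overlap`` is the
    fraction of pixel sample points falling inside the volume.
    """
    pts_mm = _volume_points_mm(spec, volume.extent)
    idx = mm_to_index(pts_mm, volume)
    values, inside = trilinear_sample(np.asarray(volume.grid, dtype=float), idx)
    n = spec.resolution
    pixels = values.reshape(n, n)
    overlap = float(np.mean(inside))
    return SliceImage(pixels=pixels, label=spec.pose, overlap=overlap)


def overlap_fraction(volume: Volume, spec: SlicePlaneSpec) -> float:
    """Fraction of the slice's pixel sample points inside the volume."""
    pts_mm = _volume_points_mm(spec, volume.extent)
    idx = mm_to_index(pts_mm, volume)
    shape = np.asarray(volume.grid.shape)
    inside = np.all((idx >= 0.0) & (idx <= shape - 1.0), axis=1)
    return float(np.mean(inside))


# ---------------------------------------------------------------------------
# PNG export
# ---------------------------------------------------------------------------

def save_slice_png(pixels: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] grayscale image as 8-bit PNG."""
    q = np.clip(np.rint(np.asarray(pixels, dtype=float) * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), q)


def load_slice_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG back to a [0, 1] float array."""
    q = iio.imread(Path(path))
    if q.ndim == 3:
        q = q[..., 0]
    return q.astype(np.float64) / 255.0
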