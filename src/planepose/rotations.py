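"""SO(3) machinery for plane-pose regression.

Rotations are represented three ways in this package:

* a 3x3 orthonormal matrix ``R`` with ``det(R) = +1`` (the canonical form),
* the continuous 6D representation ``(r1..r6)``: the first two columns of
  ``R`` flattened column-major.  Any pair of non-degenerate 3-vectors maps
  back onto SO(3) through Gram-Schmidt orthonormalisation, which is what
  makes this representation suitable as a regression target, and
* Euler angles in degrees, used only in labels and reports.

The Euler convention used throughout the package is intrinsic Z-X-Y
(:data:`EULER_CONVENTION`), matching a right-handed game-engine-style
export.  It is a single named constant so datasets stay self-describing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation as _ScipyRotation

__all__ = [
    "EULER_CONVENTION",
    "SUPPORTED_CONVENTIONS",
    "Pose",
    "gram_schmidt_to_rotation",
    "gram_schmidt_batch",
    "rotation_to_sixd",
    "sixd_to_rotation",
    "euler_to_rotation",
    "rotation_to_euler",
    "geodesic_distance_deg",
    "random_rotation_in_range",
    "random_rotation",
    "validate_rotation",
    "is_rotation",
]

#: Intrinsic Tait-Bryan convention used for all Euler-angle labels.
EULER_CONVENTION = "ZXY"

#: Conventions accepted by the Euler conversion routines (intrinsic,
#: upper-case axis letters, each axis once).
SUPPORTED_CONVENTIONS = ("ZXY", "XYZ", "ZYX", "YXZ", "XZY", "YZX")

#: Degeneracy threshold on vector norms inside Gram-Schmidt.
DEGENERACY_EPS = 1e-8

_ORTHO_TOL = 1e-6


def validate_rotation(R: np.ndarray, tol: float = _ORTHO_TOL) -> np.ndarray:
    """Check that ``R`` is a proper rotation matrix and return it as float64.

    Raises
    ------
    ValueError
        If ``R`` is not 3x3, not orthonormal to ``tol`` (Frobenius norm of
        ``R^T R - I``), or has determinant differing from +1 by more than
        ``tol``.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation matrix must be 3x3, got shape {R.shape}")
    if not np.all(np.isfinite(R)):
        raise ValueError("rotation matrix contains non-finite entries")
    err = np.linalg.norm(R.T @ R - np.eye(3))
    if err > tol:
        raise ValueError(f"matrix is not orthonormal: ||R^T R - I||_F = {err:.3e}")
    det = np.linalg.det(R)
    if abs(det - 1.0) > tol:
        raise ValueError(f"matrix determinant {det:.6f} != +1 (improper rotation?)")
    return R


def is_rotation(R: np.ndarray, tol: float = _ORTHO_TOL) -> bool:
    """True if ``R`` satisfies the rotation-matrix invariants."""
    try:
        validate_rotation(R, tol=tol)
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# 6D representation / Gram-Schmidt
# ---------------------------------------------------------------------------

def gram_schmidt_to_rotation(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Build a rotation matrix from two 3-vectors by Gram-Schmidt.

    ``e1 = v1/||v1||``, ``u2 = v2 - (e1 . v2) e1``, ``e2 = u2/||u2||`` and
    the columns of the result are ``(e1, e2, e1 x e2)``.  The output is a
    proper rotation for any non-degenerate input pair, which is what makes
    the 6D rotation representation usable as an unconstrained network head.

    Raises
    ------
    ValueError
        If ``||v1||`` or ``||u2||`` falls below the degeneracy threshold
        (zero or near-parallel input vectors).
    """
    v1 = np.asarray(v1, dtype=float).reshape(3)
    v2 = np.asarray(v2, dtype=float).reshape(3)
    n1 = np.linalg.norm(v1)
    if n1 < DEGENERACY_EPS:
        raise ValueError(f"first Gram-Schmidt vector is degenerate (norm {n1:.3e})")
    e1 = v1 / n1
    u2 = v2 - (e1 @ v2) * e1
    n2 = np.linalg.norm(u2)
    if n2 < DEGENERACY_EPS:
        raise ValueError(
            f"second Gram-Schmidt vector is parallel to the first (residual norm {n2:.3e})"
        )
    e2 = u2 / n2
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=1)


def gram_schmidt_batch(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Vectorised Gram-Schmidt: ``(..., 3)`` pairs -> ``(..., 3, 3)`` rotations.

    Same formulas as :func:`gram_schmidt_to_rotation`; degenerate rows raise.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = np.linalg.norm(v1, axis=-1, keepdims=True)
    if np.any(n1 < DEGENERACY_EPS):
        raise ValueError("degenerate first vector in Gram-Schmidt batch")
    e1 = v1 / n1
    u2 = v2 - np.sum(e1 * v2, axis=-1, keepdims=True) * e1
    n2 = np.linalg.norm(u2, axis=-1, keepdims=True)
    if np.any(n2 < DEGENERACY_EPS):
        raise ValueError("near-parallel vector pair in Gram-Schmidt batch")
    e2 = u2 / n2
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=-1)


def rotation_to_sixd(R: np.ndarray) -> np.ndarray:
    """First two columns of ``R``, column-major: ``(r1..r6)``.

    Inverse (up to Gram-Schmidt projection) of :func:`sixd_to_rotation`.
    """
    R = validate_rotation(R)
    return np.concatenate([R[:, 0], R[:, 1]])


def sixd_to_rotation(r: np.ndarray) -> np.ndarray:
    """Reconstruct a rotation from a 6-vector via Gram-Schmidt."""
    r = np.asarray(r, dtype=float).reshape(6)
    return gram_schmidt_to_rotation(r[:3], r[3:])


# ---------------------------------------------------------------------------
# Euler angles
# ---------------------------------------------------------------------------

def _check_convention(convention: str) -> str:
    if convention not in SUPPORTED_CONVENTIONS:
        raise ValueError(
            f"unknown Euler convention {convention!r}; supported: {SUPPORTED_CONVENTIONS}"
        )
    return convention


def _angles_to_sequence(euler_deg: np.ndarray, convention: str) -> np.ndarray:
    """Reorder an (ax, ay, az) triplet into the convention's axis order."""
    order = ["XYZ".index(axis) for axis in convention]
    return np.asarray(euler_deg, dtype=float).reshape(3)[order]


def _sequence_to_angles(seq_deg: np.ndarray, convention: str) -> np.ndarray:
    out = np.empty(3)
    for value, axis in zip(seq_deg, convention):
        out["XYZ".index(axis)] = value
    return out


def euler_to_rotation(euler_deg: np.ndarray, convention: str = EULER_CONVENTION) -> np.ndarray:
    """Rotation matrix from per-axis angles ``(ax, ay, az)`` in degrees.

    ``convention`` names the intrinsic application order, e.g. the default
    ``"ZXY"`` means rotate about Z first, then the new X, then the new Y.
    """
    _check_convention(convention)
    seq = _angles_to_sequence(euler_deg, convention)
    return _ScipyRotation.from_euler(convention, seq, degrees=True).as_matrix()


def rotation_to_euler(R: np.ndarray, convention: str = EULER_CONVENTION) -> np.ndarray:
    """Per-axis Euler angles ``(ax, ay, az)`` in degrees, each in [-180, 180).

    At gimbal lock (middle angle of the sequence at +-90 deg) the third
    rotation is set to zero and its contribution folded into the first —
    a deterministic, documented tie-break.
    """
    _check_convention(convention)
    R = validate_rotation(R)
    with warnings.catch_warnings():
        # scipy warns at gimbal lock; its resolution (third angle -> 0) is
        # exactly the tie-break we document, so the warning is noise here.
        warnings.simplefilter("ignore")
        seq = _ScipyRotation.from_matrix(R).as_euler(convention, degrees=True)
    seq = np.where(seq >= 180.0, seq - 360.0, seq)
    seq = np.where(seq < -180.0, seq + 360.0, seq)
    return _sequence_to_angles(seq, convention)


# ---------------------------------------------------------------------------
# Geodesic distance
# ---------------------------------------------------------------------------

def geodesic_distance_deg(R1: np.ndarray, R2: np.ndarray) -> float | np.ndarray:
    """Geodesic (angular) distance on SO(3) in degrees, in [0, 180].

    Computed from the relative rotation ``R'' = R1^T R2`` as
    ``arccos((trace(R'') - 1) / 2)`` with the argument clamped to [-1, 1]
    to absorb floating-point rounding.  Accepts stacked inputs of shape
    ``(..., 3, 3)`` and broadcasts.
    """
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    rel = np.swapaxes(R1, -1, -2) @ R2
    trace = np.trace(rel, axis1=-2, axis2=-1)
    cos = np.clip((trace - 1.0) / 2.0, -1.0, 1.0)
    ang = np.degrees(np.arccos(cos))
    return float(ang) if ang.ndim == 0 else ang


# ---------------------------------------------------------------------------
# Random rotations
# ---------------------------------------------------------------------------

def random_rotation_in_range(
    rng: np.random.Generator,
    max_angle_per_axis: float,
    convention: str = EULER_CONVENTION,
) -> np.ndarray:
    """Rotation composed from three per-axis angles, each uniform in
    ``[-max_angle_per_axis, +max_angle_per_axis]`` degrees, applied in the
    given intrinsic Euler convention.  Deterministic given the generator
    state; ``max_angle_per_axis = 0`` yields the identity.
    """
    if not (0.0 <= max_angle_per_axis <= 180.0):
        raise ValueError(
            f"max_angle_per_axis must lie in [0, 180], got {max_angle_per_axis}"
        )
    angles = rng.uniform(-max_angle_per_axis, max_angle_per_axis, size=3)
    return euler_to_rotation(angles, convention=convention)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform random rotation (used for property checks)."""
    return _ScipyRotation.random(rng=rng).as_matrix()


# ---------------------------------------------------------------------------
# Pose
# ---------------------------------------------------------------------------

@dataclass
class Pose:
    """Rigid pose of a slicing plane relative to the volume centre.

    Attributes
    ----------
    rotation
        3x3 proper rotation matrix.
    translation
        3-vector in normalised coordinates (each component in [-1, 1] for
        poses whose centre lies inside the volume).
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = validate_rotation(self.rotation)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise ValueError("pose translation contains non-finite components")
        self.translation = t

    @classmethod
    def identity(cls) -> "Pose":
        return cls()

    @classmethod
    def from_euler(
        cls,
        euler_deg: np.ndarray,
        translation: np.ndarray = (0.0, 0.0, 0.0),
        convention: str = EULER_CONVENTION,
    ) -> "Pose":
        return cls(euler_to_rotation(euler_deg, convention), np.asarray(translation, float))

    def euler(self, convention: str = EULER_CONVENTION) -> np.ndarray:
        """Euler angles (ax, ay, az) in degrees under ``convention``."""
        return rotation_to_euler(self.rotation, convention)

    def sixd(self) -> np.ndarray:
        return rotation_to_sixd(self.rotation)

    def as_target(self) -> np.ndarray:
        """9-vector regression target ``(t1, t2, t3, r1..r6)``."""
        return np.concatenate([self.translation, self.sixd()])

    @classmethod
    def from_target(cls, theta: np.ndarray) -> "Pose":
        """Inverse of :meth:`as_target`; applies Gram-Schmidt to ``r1..r6``."""
        theta = np.asarray(theta, dtype=float).reshape(9)
        return cls(sixd_to_rotation(theta[3:]), theta[:3])
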