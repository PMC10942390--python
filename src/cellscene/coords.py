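"""Rotation/translation conventions and the tomogram-to-engine frame conversion.

Everything upstream (tomograms, atomic structures, parametric surfaces) lives in
a right-handed frame with coordinates in ångströms.  Game engines conventionally
use a left-handed Z-up frame with rotations expressed as a (roll, pitch, yaw)
rotator in degrees.  This module owns both conventions and the bridge between
them:

* ``euler_to_rotation`` — the az/alt/phi Euler triplet used by subtomogram
  refinement (intrinsic ZXZ, ``R = Rz(az)·Rx(alt)·Rz(phi)``).
* ``flip_handedness`` — conjugation by a single axis mirror (Y by default),
  which converts a right-handed rotation into its left-handed counterpart.
* ``rotation_to_rotator`` / ``rotator_to_rotation`` — the engine rotator
  decomposition, composed as ``Yaw(z)·Pitch(y)·Roll(x)``.
* ``tomo_to_engine_position`` — voxel → Å → engine-unit chain, with the
  tomogram center mapping to the engine origin.

All angles cross module boundaries in degrees; matrices are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "InvalidAngleError",
    "InvalidRotationError",
    "Transform3D",
    "EngineTransform",
    "TomogramFrame",
    "Placement",
    "MIRROR_Y",
    "rotation_about_axis",
    "Rx",
    "Ry",
    "Rz",
    "euler_to_rotation",
    "flip_handedness",
    "rotator_to_rotation",
    "rotation_to_rotator",
    "normalize_angle",
    "tomo_to_engine_position",
    "compose",
    "invert",
]

_ORTHO_TOL = 1e-9


class InvalidAngleError(ValueError):
    """An Euler angle is NaN or infinite."""


class InvalidRotationError(ValueError):
    """A matrix claimed to be a rotation is not orthonormal with det +1."""


def _check_rotation(R: np.ndarray, tol: float = _ORTHO_TOL) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.all(np.isfinite(R)):
        raise InvalidRotationError(f"expected a finite 3x3 matrix, got shape {R.shape}")
    err = np.max(np.abs(R.T @ R - np.eye(3)))
    if err > tol:
        raise InvalidRotationError(f"matrix is not orthonormal (|R^T R - I|_inf = {err:.3g})")
    det = np.linalg.det(R)
    if abs(det - 1.0) > max(tol, 1e-9):
        raise InvalidRotationError(f"matrix has det {det:.6f}, expected +1 (improper rotation?)")
    return R


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-hand-rule rotation by ``angle_deg`` about an arbitrary axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be nonzero")
    x, y, z = axis / n
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def Rx(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def Ry(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def Rz(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


#: Mirror matrix used for the right-handed -> left-handed conversion.
MIRROR_Y = np.diag([1.0, -1.0, 1.0])


@dataclass(frozen=True)
class Transform3D:
    """Rigid transform in the right-handed source (tomogram/structure) frame.

    ``rotation`` is a proper orthonormal 3x3 matrix, ``translation`` is in Å.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = _check_rotation(self.rotation)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise ValueError("translation must be finite")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "Transform3D":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point or an (N, 3) array of points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        H = np.eye(4)
        H[:3, :3] = self.rotation
        H[:3, 3] = self.translation
        return H

    def isclose(self, other: "Transform3D", tol: float = 1e-9) -> bool:
        return (
            np.max(np.abs(self.rotation - other.rotation)) <= tol
            and np.max(np.abs(self.translation - other.translation)) <= tol
        )


def normalize_angle(angle_deg: float) -> float:
    """Normalize an angle in degrees to the half-open interval (-180, 180]."""
    a = (float(angle_deg) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass(frozen=True)
class EngineTransform:
    """Placement in the left-handed Z-up engine frame.

    ``rotator`` is (roll, pitch, yaw) in degrees, each normalized to
    (-180, 180]; ``scale`` is a positive uniform scale factor.
    """

    location: np.ndarray
    rotator: tuple[float, float, float]
    scale: float = 1.0

    def __post_init__(self) -> None:
        loc = np.asarray(self.location, dtype=float).reshape(3)
        if not np.all(np.isfinite(loc)):
            raise ValueError("location must be finite")
        rot = tuple(normalize_angle(a) for a in self.rotator)
        if len(rot) != 3:
            raise ValueError("rotator must be (roll, pitch, yaw)")
        if not (self.scale > 0):
            raise ValueError(f"scale must be > 0, got {self.scale}")
        object.__setattr__(self, "location", loc)
        object.__setattr__(self, "rotator", rot)

    @classmethod
    def identity(cls) -> "EngineTransform":
        return cls(np.zeros(3), (0.0, 0.0, 0.0), 1.0)


@dataclass(frozen=True)
class TomogramFrame:
    """Voxel grid geometry of a tomogram plus the Å -> engine-unit scale."""

    dims: np.ndarray
    apix: float
    world_scale: float = 1.0

    def __post_init__(self) -> None:
        dims = np.asarray(self.dims, dtype=float).reshape(3)
        if np.any(dims < 1):
            raise ValueError(f"dims must all be >= 1, got {dims}")
        if not (self.apix > 0):
            raise ValueError(f"apix must be > 0, got {self.apix}")
        if not (self.world_scale > 0):
            raise ValueError(f"world_scale must be > 0, got {self.world_scale}")
        object.__setattr__(self, "dims", dims)


class Placement(NamedTuple):
    """A mesh reference plus its rigid placement in the source frame (Å)."""

    mesh_id: str
    transform: Transform3D


def euler_to_rotation(az: float, alt: float, phi: float) -> np.ndarray:
    """Rotation matrix from an az/alt/phi triplet (degrees).

    Convention: intrinsic ZXZ, ``R = Rz(az) @ Rx(alt) @ Rz(phi)`` — the triplet
    layout used by subtomogram-refinement alignment records.
    """
    for name, a in (("az", az), ("alt", alt), ("phi", phi)):
        if not np.isfinite(a):
            raise InvalidAngleError(f"angle {name!r} is not finite: {a}")
    return Rz(az) @ Rx(alt) @ Rz(phi)


def flip_handedness(R: np.ndarray, mirror_axis: str = "y") -> np.ndarray:
    """Conjugate a rotation by a single-axis mirror: ``M @ R @ M``.

    Converts between the right-handed source frame and the left-handed engine
    frame.  The result is again a proper rotation, and the operation is an
    involution.  ``mirror_axis`` selects which axis is mirrored (default y).
    """
    R = _check_rotation(R)
    try:
        i = "xyz".index(mirror_axis)
    except ValueError:
        raise ValueError(f"mirror_axis must be one of 'x', 'y', 'z', got {mirror_axis!r}") from None
    d = np.ones(3)
    d[i] = -1.0
    M = np.diag(d)
    return M @ R @ M


def rotator_to_rotation(roll: float, pitch: float, yaw: float) -> np.ndarray:
    """Compose an engine rotator into a matrix: ``Rz(yaw) @ Ry(pitch) @ Rx(roll)``."""
    for name, a in (("roll", roll), ("pitch", pitch), ("yaw", yaw)):
        if not np.isfinite(a):
            raise InvalidAngleError(f"angle {name!r} is not finite: {a}")
    return Rz(yaw) @ Ry(pitch) @ Rx(roll)


def rotation_to_rotator(R: np.ndarray) -> tuple[float, float, float]:
    """Decompose a rotation into the engine (roll, pitch, yaw) rotator, degrees.

    Inverse of :func:`rotator_to_rotation`.  ``pitch`` lies in [-90, 90]; at the
    gimbal singularity (|pitch| = 90) the tie-break sets ``roll = 0``.
    """
    R = _check_rotation(R)
    sp = np.clip(-R[2, 0], -1.0, 1.0)
    pitch = np.rad2deg(np.arcsin(sp))
    if abs(sp) >= 1.0 - 1e-12:
        # gimbal lock: only yaw - sign(pitch)*roll is determined; put it in yaw
        roll = 0.0
        yaw = np.rad2deg(np.arctan2(-R[0, 1], R[1, 1]))
    else:
        roll = np.rad2deg(np.arctan2(R[2, 1], R[2, 2]))
        yaw = np.rad2deg(np.arctan2(R[1, 0], R[0, 0]))
    return (normalize_angle(roll), normalize_angle(pitch), normalize_angle(yaw))


def tomo_to_engine_position(
    center_voxel: np.ndarray, frame: TomogramFrame, mirror_axis: str = "y"
) -> np.ndarray:
    """Map a voxel coordinate to an engine-frame position.

    ``world_scale * M * (apix * (center_voxel - dims/2))`` with M the axis
    mirror; the tomogram center maps to the engine origin.
    """
    cv = np.asarray(center_voxel, dtype=float).reshape(3)
    i = "xyz".index(mirror_axis)
    d = np.ones(3)
    d[i] = -1.0
    return frame.world_scale * d * (frame.apix * (cv - frame.dims / 2.0))


def compose(a: Transform3D, b: Transform3D) -> Transform3D:
    """Transform applying ``b`` first, then ``a``."""
    return Transform3D(a.rotation @ b.rotation, a.rotation @ b.translation + a.translation)


def invert(a: Transform3D) -> Transform3D:
    Rt = a.rotation.T
    return Transform3D(Rt, -Rt @ a.translation)
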