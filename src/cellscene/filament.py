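"""Helical filament placement along arbitrary paths.

A filament (actin, a pilus, a flagellum) is rendered as one repeating segment
mesh placed every ``rise`` Å along a traced path, each copy rotated by
``twist`` degrees about the local tangent relative to its predecessor.  The
moving frame along the path is computed with the double-reflection
rotation-minimizing-frame (RMF) method, which — unlike Frenet frames — is
well defined on straight runs and does not flip at inflection points, both of
which occur routinely in paths traced from tomograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .coords import Placement, Transform3D, rotation_about_axis
from .structio import Path3D

__all__ = [
    "DegeneratePathError",
    "InvalidSeedError",
    "HelicalParams",
    "PathFrame",
    "resample_path",
    "transport_frames",
    "place_filament",
]


class DegeneratePathError(ValueError):
    """Path has (numerically) zero length."""


class InvalidSeedError(ValueError):
    """Seed normal is parallel to the first tangent."""


@dataclass(frozen=True)
class HelicalParams:
    """Helical repeat: axial rise (Å) and twist (degrees) per segment."""

    rise: float
    twist: float = 0.0
    seed_normal: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.rise > 0):
            raise ValueError(f"rise must be > 0 Å, got {self.rise}")
        if self.seed_normal is not None:
            object.__setattr__(
                self, "seed_normal", np.asarray(self.seed_normal, dtype=float).reshape(3)
            )


@dataclass(frozen=True)
class PathFrame:
    """Orthonormal right-handed moving frame at one path sample."""

    point: np.ndarray
    tangent: np.ndarray
    normal: np.ndarray
    binormal: np.ndarray

    def matrix(self) -> np.ndarray:
        """Rotation with columns (normal, binormal, tangent): local +z = tangent."""
        return np.column_stack([self.normal, self.binormal, self.tangent])


def _polyline(path: Path3D) -> np.ndarray:
    pts = path.points
    if path.closed:
        pts = np.vstack([pts, pts[:1]])
    return pts


def resample_path(path: Path3D, spacing: float) -> list[tuple[np.ndarray, np.ndarray]]:
    """Resample a polyline at uniform arc-length ``spacing``.

    Samples sit at arc lengths 0, s, 2s, ... ≤ total length; the start is
    always included and the end only when it falls on the grid (within 1e-6).
    Tangents are chord-interpolated: per-vertex tangents are the normalized
    mean of adjacent segment directions, blended linearly within a segment.
    A path shorter than one spacing yields a single start sample and a warning.
    """
    if not (spacing > 0):
        raise ValueError(f"spacing must be > 0, got {spacing}")
    pts = _polyline(path)
    seg = np.diff(pts, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    L = float(seglen.sum())
    if L <= 1e-9:
        raise DegeneratePathError("path has zero length")
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    dirs = seg / seglen[:, None]
    # vertex tangents: mean of adjacent segment directions, normalized
    vtan = np.empty_like(pts)
    vtan[0] = dirs[0]
    vtan[-1] = dirs[-1]
    for i in range(1, len(pts) - 1):
        v = dirs[i - 1] + dirs[i]
        n = np.linalg.norm(v)
        vtan[i] = v / n if n > 1e-12 else dirs[i]
    if path.closed:
        v = dirs[-1] + dirs[0]
        n = np.linalg.norm(v)
        vtan[0] = vtan[-1] = v / n if n > 1e-12 else dirs[0]

    n_steps = int(np.floor(L / spacing + 1e-6))
    if n_steps == 0:
        warnings.warn(
            f"path length {L:.3g} Å is shorter than one spacing ({spacing:.3g} Å); "
            "emitting a single frame at the start",
            stacklevel=2,
        )
    svals = np.minimum(np.arange(n_steps + 1) * spacing, L)

    samples = []
    for s in svals:
        i = min(int(np.searchsorted(cum, s, side="right")) - 1, len(seglen) - 1)
        f = (s - cum[i]) / seglen[i]
        point = pts[i] + f * seg[i]
        t = (1.0 - f) * vtan[i] + f * vtan[i + 1]
        t = t / np.linalg.norm(t)
        samples.append((point, t))
    return samples


def _default_seed_normal(t0: np.ndarray) -> np.ndarray:
    e = np.zeros(3)
    e[int(np.argmin(np.abs(t0)))] = 1.0
    n = e - np.dot(e, t0) * t0
    return n / np.linalg.norm(n)


def transport_frames(
    samples: list[tuple[np.ndarray, np.ndarray]],
    seed_normal: np.ndarray | None = None,
) -> list[PathFrame]:
    """Rotation-minimizing frames along sampled (point, tangent) pairs.

    Uses the double-reflection method: each step reflects the previous frame
    through the chord bisector plane and then through the bisector of the
    reflected and true next tangent.  The transported normal accumulates no
    rotation about the tangent (second-order accurate in the step size).
    """
    if not samples:
        raise ValueError("need at least one sample")
    p0, t0 = (np.asarray(v, dtype=float) for v in samples[0])
    t0 = t0 / np.linalg.norm(t0)
    if seed_normal is None:
        n0 = _default_seed_normal(t0)
    else:
        n0 = np.asarray(seed_normal, dtype=float).reshape(3)
        nn = np.linalg.norm(n0)
        if nn == 0 or np.linalg.norm(np.cross(n0 / nn, t0)) < 1e-4:
            raise InvalidSeedError("seed normal is (nearly) parallel to the first tangent")
        n0 = n0 - np.dot(n0, t0) * t0
        n0 = n0 / np.linalg.norm(n0)

    frames = [PathFrame(p0, t0, n0, np.cross(t0, n0))]
    for k in range(1, len(samples)):
        pk, tk = (np.asarray(v, dtype=float) for v in samples[k])
        tk = tk / np.linalg.norm(tk)
        prev = frames[-1]
        v1 = pk - prev.point
        c1 = float(v1 @ v1)
        if c1 < 1e-24:  # coincident samples: carry the frame over
            r_next = prev.normal
        else:
            rL = prev.normal - (2.0 / c1) * (v1 @ prev.normal) * v1
            tL = prev.tangent - (2.0 / c1) * (v1 @ prev.tangent) * v1
            v2 = tk - tL
            c2 = float(v2 @ v2)
            r_next = rL if c2 < 1e-24 else rL - (2.0 / c2) * (v2 @ rL) * v2
        r_next = r_next - (r_next @ tk) * tk
        r_next = r_next / np.linalg.norm(r_next)
        frames.append(PathFrame(pk, tk, r_next, np.cross(tk, r_next)))
    return frames


def place_filament(
    path: Path3D,
    params: HelicalParams,
    mesh_id: str,
    close_twist: bool = False,
) -> list[Placement]:
    """Place one segment mesh per helical repeat along ``path``.

    Segment k sits at resampled point k with rotation
    ``frame_k · Rz(k · twist)`` — i.e. the RMF frame (local +z along the
    tangent) composed with the accumulated helical twist about the tangent.
    With ``close_twist`` on a closed path, twist is rounded so the total twist
    at closure is a multiple of 360°.
    """
    samples = resample_path(path, params.rise)
    frames = transport_frames(samples, params.seed_normal)
    twist = params.twist
    if close_twist and path.closed:
        k = len(frames)
        total = twist * k
        twist = round(total / 360.0) * 360.0 / k
    placements = []
    for k, fr in enumerate(frames):
        R = fr.matrix() @ rotation_about_axis([0.0, 0.0, 1.0], k * twist)
        placements.append(Placement(mesh_id, Transform3D(R, fr.point)))
    return placements
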