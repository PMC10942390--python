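"""Organelle membranes as parametric surfaces tiled with square lipid patches.

A membrane shape (sphere, tube, flat sheet, or cisterna — a disc with a
toroidal rim, the basic Golgi/thylakoid shape) is described analytically by a
point map S(u, v) and an outward unit normal N(u, v).  The surface is tiled
with square lipid-patch placements at near-uniform spacing; each patch carries
its center, normal, and in-plane orientation.  :func:`bilayer` turns the
mid-surface patches into two leaflets offset by ±thickness/2 along the normal,
the inner leaflet flipped so headgroups face outward on both sides.  Membrane
proteins are inserted normal-aligned at a chosen (u, v), optionally clearing
the lipid patches they overlap.

The lipid patch itself is external content (a mesh id with a stated edge
length); this module owns only the geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .coords import Placement, Transform3D, rotation_about_axis
from .structio import Path3D

__all__ = [
    "ParameterError",
    "TooCoarseError",
    "DomainError",
    "ParametricSurface",
    "SurfacePatch",
    "make_surface",
    "tile_surface",
    "bilayer",
    "insert_membrane_protein",
]


class ParameterError(ValueError):
    """Missing or out-of-range surface/bilayer parameter."""


class TooCoarseError(ValueError):
    """Patch edge is larger than the surface can accommodate."""


class DomainError(ValueError):
    """(u, v) outside the surface's parameter domain."""


@dataclass(frozen=True)
class ParametricSurface:
    """Analytic surface: point map S(u, v) and outward unit normal N(u, v)."""

    kind: str
    params: dict
    u_domain: tuple[float, float]
    v_domain: tuple[float, float]
    _S: Callable[[float, float], np.ndarray]
    _N: Callable[[float, float], np.ndarray]
    area: float | None = None  # analytic area where known
    min_curvature_radius: float | None = None

    def evaluate(self, u: float, v: float) -> np.ndarray:
        self._check_domain(u, v)
        return self._S(u, v)

    def normal(self, u: float, v: float) -> np.ndarray:
        self._check_domain(u, v)
        return self._N(u, v)

    def _check_domain(self, u: float, v: float) -> None:
        (u0, u1), (v0, v1) = self.u_domain, self.v_domain
        tol_u = 1e-9 * max(1.0, abs(u1 - u0))
        tol_v = 1e-9 * max(1.0, abs(v1 - v0))
        if not (u0 - tol_u <= u <= u1 + tol_u) or not (v0 - tol_v <= v <= v1 + tol_v):
            raise DomainError(
                f"(u={u}, v={v}) outside domain [{u0}, {u1}] x [{v0}, {v1}] of {self.kind}"
            )


@dataclass(frozen=True)
class SurfacePatch:
    """One square lipid patch on the mid-surface."""

    center: np.ndarray
    normal: np.ndarray
    in_plane_x: np.ndarray
    edge: float
    leaflet: str = "outer"

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float).reshape(3)
        x = np.asarray(self.in_plane_x, dtype=float).reshape(3)
        c = np.asarray(self.center, dtype=float).reshape(3)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9 or abs(np.linalg.norm(x) - 1.0) > 1e-9:
            raise ValueError("normal and in_plane_x must be unit vectors")
        if abs(float(n @ x)) > 1e-9:
            raise ValueError("in_plane_x must be perpendicular to normal")
        if not (self.edge > 0):
            raise ValueError(f"edge must be > 0, got {self.edge}")
        if self.leaflet not in ("outer", "inner"):
            raise ValueError(f"leaflet must be 'outer' or 'inner', got {self.leaflet!r}")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "in_plane_x", x)

    def frame(self) -> np.ndarray:
        """Rotation with local +x = in_plane_x and +z = normal."""
        y = np.cross(self.normal, self.in_plane_x)
        return np.column_stack([self.in_plane_x, y, self.normal])


def _need(params: dict, key: str, kind: str) -> float:
    if key not in params:
        raise ParameterError(f"{kind} surface requires parameter {key!r}")
    return params[key]


def _positive(value: float, key: str) -> float:
    if not (np.isscalar(value) and value > 0):
        raise ParameterError(f"parameter {key!r} must be a positive scalar, got {value}")
    return float(value)


def make_surface(kind: str, params: dict) -> ParametricSurface:
    """Construct a parametric membrane surface.

    kinds and parameters (Å):

    * ``sphere``   — ``radius``; u = azimuth [0, 2π), v = polar [0, π].
    * ``sheet``    — ``width``, ``height``; u ∈ [0, W], v ∈ [0, H], z = 0.
    * ``tube``     — ``path`` (:class:`Path3D`), ``radius``; u = arc length,
      v = angle around the tube; framed by rotation-minimizing transport.
    * ``cisterna`` — ``disc_radius``, ``rim_radius``; surface of revolution of
      a flat-top/flat-bottom profile with a semicircular rim; u = azimuth,
      v = profile arc length.
    """
    if kind == "sphere":
        r = _positive(_need(params, "radius", kind), "radius")

        def S(u, v, r=r):
            sv = np.sin(v)
            return r * np.array([sv * np.cos(u), sv * np.sin(u), np.cos(v)])

        def N(u, v):
            sv = np.sin(v)
            return np.array([sv * np.cos(u), sv * np.sin(u), np.cos(v)])

        return ParametricSurface(
            kind, dict(params), (0.0, 2 * np.pi), (0.0, np.pi), S, N,
            area=4 * np.pi * r**2, min_curvature_radius=r,
        )

    if kind == "sheet":
        w = _positive(_need(params, "width", kind), "width")
        h = _positive(_need(params, "height", kind), "height")

        def S(u, v, w=w, h=h):
            return np.array([u - w / 2.0, v - h / 2.0, 0.0])

        def N(u, v):
            return np.array([0.0, 0.0, 1.0])

        return ParametricSurface(kind, dict(params), (0.0, w), (0.0, h), S, N, area=w * h)

    if kind == "tube":
        path = _need(params, "path", kind)
        if not isinstance(path, Path3D):
            raise ParameterError("tube surface requires a Path3D under 'path'")
        r = _positive(_need(params, "radius", kind), "radius")
        from .filament import resample_path, transport_frames

        L = path.length()
        step = L / max(500, 20 * int(L / r + 1))
        frames = transport_frames(resample_path(path, step))
        s_grid = np.array([min(k * step, L) for k in range(len(frames))])
        C = np.array([f.point for f in frames])
        Nv = np.array([f.normal for f in frames])
        Bv = np.array([f.binormal for f in frames])

        def _interp(arr, u):
            i = min(int(np.searchsorted(s_grid, u, side="right")) - 1, len(s_grid) - 2)
            i = max(i, 0)
            f = (u - s_grid[i]) / (s_grid[i + 1] - s_grid[i])
            f = np.clip(f, 0.0, 1.0)
            return (1 - f) * arr[i] + f * arr[i + 1]

        def S(u, v):
            n = _interp(Nv, u)
            b = _interp(Bv, u)
            rad = np.cos(v) * n + np.sin(v) * b
            return _interp(C, u) + r * rad / np.linalg.norm(rad)

        def N(u, v):
            n = _interp(Nv, u)
            b = _interp(Bv, u)
            rad = np.cos(v) * n + np.sin(v) * b
            return rad / np.linalg.norm(rad)

        return ParametricSurface(
            kind, dict(params), (0.0, L), (0.0, 2 * np.pi), S, N,
            min_curvature_radius=r,
        )

    if kind == "cisterna":
        rd = _positive(_need(params, "disc_radius", kind), "disc_radius")
        rr = _positive(_need(params, "rim_radius", kind), "rim_radius")
        Lp = 2 * rd + np.pi * rr  # profile arc length: top disc, rim, bottom disc

        def _profile(v, rd=rd, rr=rr):
            """(rho, z, n_rho, n_z) of the revolved profile at arc length v."""
            if v <= rd:
                return v, rr, 0.0, 1.0
            if v <= rd + np.pi * rr:
                phi = np.pi / 2 - (v - rd) / rr
                return rd + rr * np.cos(phi), rr * np.sin(phi), np.cos(phi), np.sin(phi)
            w = v - rd - np.pi * rr
            return rd - w, -rr, 0.0, -1.0

        def S(u, v):
            rho, z, _, _ = _profile(v)
            return np.array([rho * np.cos(u), rho * np.sin(u), z])

        def N(u, v):
            _, _, nr, nz = _profile(v)
            return np.array([nr * np.cos(u), nr * np.sin(u), nz])

        area = 2 * np.pi * rd**2 + 2 * np.pi**2 * rr * rd + 4 * np.pi * rr**2
        return ParametricSurface(
            kind, dict(params), (0.0, 2 * np.pi), (0.0, Lp), S, N,
            area=area, min_curvature_radius=rr,
        )

    raise ParameterError(f"unknown surface kind {kind!r}")


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def tile_surface(surface: ParametricSurface, patch_edge: float) -> list[SurfacePatch]:
    """Tile a surface with square patches at near-uniform ``patch_edge`` spacing.

    Spheres use a deterministic Fibonacci lattice with
    ``round(4πr²/edge²)`` points; the other kinds use arc-length-corrected
    (u, v) grids.  Patch in-plane orientation follows the local u-direction
    (local east on the sphere) so neighbouring patches vary smoothly.
    """
    if not (patch_edge > 0):
        raise ParameterError(f"patch_edge must be > 0, got {patch_edge}")
    if surface.min_curvature_radius is not None and patch_edge > surface.min_curvature_radius:
        warnings.warn(
            f"patch_edge {patch_edge:.3g} Å exceeds the minimal curvature radius "
            f"({surface.min_curvature_radius:.3g} Å); patches will overlap or gap",
            stacklevel=2,
        )

    if surface.kind == "sphere":
        r = surface.params["radius"]
        n = int(round(4 * np.pi * r**2 / patch_edge**2))
        if n < 1:
            raise TooCoarseError(f"patch_edge {patch_edge} too large for sphere radius {r}")
        patches = []
        for i in range(n):
            z = 1.0 - 2.0 * (i + 0.5) / n
            az = i * _GOLDEN_ANGLE
            sv = np.sqrt(max(0.0, 1.0 - z * z))
            normal = np.array([sv * np.cos(az), sv * np.sin(az), z])
            east = np.array([-np.sin(az), np.cos(az), 0.0])
            if np.linalg.norm(np.cross(east, normal)) < 1e-9:  # polar fallback
                east = np.array([1.0, 0.0, 0.0])
            east = east - (east @ normal) * normal
            east /= np.linalg.norm(east)
            patches.append(SurfacePatch(r * normal, normal, east, patch_edge))
        return patches

    if surface.kind == "sheet":
        w, h = surface.params["width"], surface.params["height"]
        if patch_edge > w or patch_edge > h:
            raise TooCoarseError(f"patch_edge {patch_edge} exceeds sheet dimensions {w}x{h}")
        nx, ny = max(1, round(w / patch_edge)), max(1, round(h / patch_edge))
        patches = []
        for j in range(ny):
            v = (j + 0.5) * h / ny
            for i in range(nx):
                u = (i + 0.5) * w / nx
                patches.append(
                    SurfacePatch(
                        surface.evaluate(u, v), np.array([0.0, 0.0, 1.0]),
                        np.array([1.0, 0.0, 0.0]), patch_edge,
                    )
                )
        return patches

    if surface.kind == "tube":
        L = surface.u_domain[1]
        r = surface.params["radius"]
        n_rings = int(round(L / patch_edge))
        n_around = int(round(2 * np.pi * r / patch_edge))
        if n_rings < 1 or n_around < 1:
            raise TooCoarseError(f"patch_edge {patch_edge} too large for tube (L={L}, r={r})")
        patches = []
        for j in range(n_rings):
            u = (j + 0.5) * L / n_rings
            for i in range(n_around):
                v = (i + 0.5) * 2 * np.pi / n_around
                patches.append(_patch_at(surface, u, v, patch_edge))
        return patches

    if surface.kind == "cisterna":
        Lp = surface.v_domain[1]
        n_bands = int(round(Lp / patch_edge))
        if n_bands < 1:
            raise TooCoarseError(f"patch_edge {patch_edge} too large for cisterna profile {Lp:.3g}")
        patches = []
        for j in range(n_bands):
            v = (j + 0.5) * Lp / n_bands
            rho = np.linalg.norm(surface.evaluate(0.0, v)[:2])
            n_around = max(1, int(round(2 * np.pi * rho / patch_edge)))
            for i in range(n_around):
                u = (i + 0.5) * 2 * np.pi / n_around
                patches.append(_patch_at(surface, u, v, patch_edge))
        return patches

    raise ParameterError(f"no tiling rule for surface kind {surface.kind!r}")


def _patch_at(surface: ParametricSurface, u: float, v: float, edge: float) -> SurfacePatch:
    """Patch at (u, v) with in-plane x along the (numerical) u-direction."""
    p = surface.evaluate(u, v)
    n = surface.normal(u, v)
    x = _u_direction(surface, u, v, n)
    return SurfacePatch(p, n, x, edge)


def _u_direction(surface: ParametricSurface, u: float, v: float, n: np.ndarray) -> np.ndarray:
    u0, u1 = surface.u_domain
    du = 1e-6 * max(1.0, u1 - u0)
    a = max(u0, u - du)
    b = min(u1, u + du)
    su = surface.evaluate(b, v) - surface.evaluate(a, v)
    su = su - (su @ n) * n
    nrm = np.linalg.norm(su)
    if nrm < 1e-12:  # degenerate (e.g. revolution axis): any perpendicular
        e = np.zeros(3)
        e[int(np.argmin(np.abs(n)))] = 1.0
        su = e - (e @ n) * n
        nrm = np.linalg.norm(su)
    return su / nrm


# ---------------------------------------------------------------------------
# bilayer assembly and protein insertion
# ---------------------------------------------------------------------------

def bilayer(
    patches: list[SurfacePatch], thickness: float, mesh_id: str
) -> list[Placement]:
    """Two leaflet placements per mid-surface patch (source frame, Å).

    Outer leaflet at +thickness/2 along the patch normal; inner leaflet at
    −thickness/2, flipped 180° about the patch's in-plane x axis so headgroups
    point outward on both leaflets.
    """
    if not (thickness > 0):
        raise ParameterError(f"thickness must be > 0 Å, got {thickness}")
    half = thickness / 2.0
    placements = []
    for p in patches:
        R_out = p.frame()
        placements.append(Placement(mesh_id, Transform3D(R_out, p.center + half * p.normal)))
        R_in = rotation_about_axis(p.in_plane_x, 180.0) @ R_out
        placements.append(Placement(mesh_id, Transform3D(R_in, p.center - half * p.normal)))
    return placements


def insert_membrane_protein(
    surface: ParametricSurface,
    u: float,
    v: float,
    mesh_id: str,
    clearance: float,
    patches: list[SurfacePatch],
) -> tuple[Placement, list[SurfacePatch]]:
    """Place a membrane protein at S(u, v), normal-aligned, clearing lipids.

    The protein's local +z is aligned to N(u, v) and its in-plane x to the
    local u-direction.  All patches whose centers lie strictly within
    ``clearance`` Å of the insertion point are removed from the returned list.
    """
    if clearance < 0:
        raise ParameterError(f"clearance must be >= 0, got {clearance}")
    p = surface.evaluate(u, v)  # raises DomainError outside the domain
    n = surface.normal(u, v)
    x = _u_direction(surface, u, v, n)
    R = np.column_stack([x, np.cross(n, x), n])
    placement = Placement(mesh_id, Transform3D(R, p))
    kept = [q for q in patches if np.linalg.norm(q.center - p) >= clearance]
    return placement, kept
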