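"""Omnidirectional-stereo (ODS) panorama camera rig.

A stereo 360° frame is an equirectangular panorama rendered once per eye.
A fixed left/right camera offset only gives correct stereo looking forward:
turn 180° and the eyes swap.  In an ODS rig the eye baseline rotates with the
viewing azimuth — for view direction v(θ) the eyes sit at ±(ipd/2) along the
horizontal perpendicular of v(θ) — so stereo is correct in every horizontal
direction (and, unavoidably, degenerate at the poles).

The full frame is split into an ncols × nrows tile grid (the working default
follows the 6000×3000-pixel, 10×6 production setup); each tile is rendered by
a pinhole camera aimed at the tile's angular center with the eye offset
evaluated at that yaw (piecewise-constant ODS approximation), and the
externally rendered tile images are reassembled by pure placement.

Conventions: right-handed Z-up rig frame; yaw 0 at the frame's horizontal
center increasing rightward, x → yaw ∈ [−180, 180); y → pitch ∈ [90, −90];
rig cameras have roll 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TilingError",
    "AssemblyError",
    "TileSpec",
    "CameraPose",
    "tile_grid",
    "ods_eye_position",
    "tile_camera",
    "assemble_tiles",
    "split_image",
]


class TilingError(ValueError):
    """Frame dimensions not divisible by the tile grid."""


class AssemblyError(ValueError):
    """Tile set incomplete or block sizes inconsistent."""


@dataclass(frozen=True)
class TileSpec:
    """One tile of the equirectangular frame: pixel extent plus view angles."""

    row: int
    col: int
    x0: int
    y0: int
    width: int
    height: int
    yaw_center: float
    pitch_center: float
    hfov: float
    vfov: float


@dataclass(frozen=True)
class CameraPose:
    """Camera position, engine-style rotator (roll, pitch, yaw), and FOV."""

    position: np.ndarray
    rotator: tuple[float, float, float]
    hfov: float
    vfov: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float).reshape(3))
        roll, pitch, yaw = self.rotator
        if not (-90.0 <= pitch <= 90.0):
            raise ValueError(f"pitch must be in [-90, 90], got {pitch}")
        if roll != 0.0:
            raise ValueError("rig cameras have roll 0")


def tile_grid(width: int, height: int, ncols: int, nrows: int) -> list[TileSpec]:
    """Partition a width×height equirectangular frame into ncols×nrows tiles.

    Tiles are returned in row-major order and partition the frame exactly.
    Each tile spans hfov = 360/ncols and vfov = 180/nrows degrees, centred on
    the tile's angular midpoint.
    """
    if ncols < 1 or nrows < 1:
        raise TilingError("need at least one row and one column")
    if width % ncols or height % nrows:
        raise TilingError(
            f"{width}x{height} frame not divisible into a {ncols}x{nrows} grid"
        )
    tw, th = width // ncols, height // nrows
    hfov, vfov = 360.0 / ncols, 180.0 / nrows
    tiles = []
    for r in range(nrows):
        for c in range(ncols):
            yaw = -180.0 + 360.0 * (c + 0.5) / ncols
            pitch = 90.0 - 180.0 * (r + 0.5) / nrows
            tiles.append(
                TileSpec(r, c, c * tw, r * th, tw, th, yaw, pitch, hfov, vfov)
            )
    return tiles


def ods_eye_position(
    yaw: float, ipd: float, eye: str, rig_center: np.ndarray = (0.0, 0.0, 0.0)
) -> np.ndarray:
    """Eye position for viewing azimuth ``yaw`` (degrees).

    With view direction v(θ) = (cos θ, sin θ, 0) in the right-handed Z-up rig
    frame, the right eye sits at rig_center + (ipd/2)(sin θ, −cos θ, 0) and the
    left eye mirrored — the baseline rotates with the view, so the eyes never
    swap and the baseline is always perpendicular to v(θ).
    """
    if not (ipd > 0):
        raise ValueError(f"ipd must be > 0, got {ipd}")
    if eye not in ("left", "right"):
        raise ValueError(f"eye must be 'left' or 'right', got {eye!r}")
    th = np.deg2rad(yaw)
    offset = (ipd / 2.0) * np.array([np.sin(th), -np.cos(th), 0.0])
    sign = 1.0 if eye == "right" else -1.0
    return np.asarray(rig_center, dtype=float).reshape(3) + sign * offset


def tile_camera(
    tile: TileSpec, eye: str, ipd: float, rig_center: np.ndarray = (0.0, 0.0, 0.0)
) -> CameraPose:
    """Pinhole camera pose rendering one tile for one eye.

    Positioned at the ODS eye point for the tile's yaw center, aimed at the
    tile's angular center (rotator (0, pitch_center, yaw_center)), with the
    tile's angular extent as field of view.
    """
    pos = ods_eye_position(tile.yaw_center, ipd, eye, rig_center)
    return CameraPose(pos, (0.0, tile.pitch_center, tile.yaw_center), tile.hfov, tile.vfov)


def assemble_tiles(tiles: list[tuple[TileSpec, np.ndarray]]) -> np.ndarray:
    """Stitch rendered tile blocks back into the full frame.

    Pure placement — pixel (x, y) of the output is the owning tile's local
    pixel, no blending.  Raises :class:`AssemblyError` on a missing tile,
    duplicate coverage, or a block whose shape disagrees with its spec.
    """
    if not tiles:
        raise AssemblyError("no tiles to assemble")
    # the grid shape is implied by each tile's angular extent
    ncols = int(round(360.0 / tiles[0][0].hfov))
    nrows = int(round(180.0 / tiles[0][0].vfov))
    if len(tiles) != ncols * nrows:
        raise AssemblyError(f"expected {ncols * nrows} tiles for a {ncols}x{nrows} grid, got {len(tiles)}")
    t0 = tiles[0][0]
    width, height = ncols * t0.width, nrows * t0.height
    block0 = np.asarray(tiles[0][1])
    out = np.zeros((height, width) + block0.shape[2:], dtype=block0.dtype)
    seen = set()
    for spec, block in tiles:
        block = np.asarray(block)
        if block.shape[:2] != (spec.height, spec.width):
            raise AssemblyError(
                f"tile ({spec.row},{spec.col}): block shape {block.shape[:2]} "
                f"!= spec {spec.height}x{spec.width}"
            )
        if (spec.row, spec.col) in seen:
            raise AssemblyError(f"duplicate tile ({spec.row},{spec.col})")
        seen.add((spec.row, spec.col))
        out[spec.y0 : spec.y0 + spec.height, spec.x0 : spec.x0 + spec.width] = block
    return out


def split_image(image: np.ndarray, ncols: int, nrows: int) -> list[tuple[TileSpec, np.ndarray]]:
    """Inverse of :func:`assemble_tiles`: cut a frame into tile blocks."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    tiles = tile_grid(w, h, ncols, nrows)
    return [
        (t, image[t.y0 : t.y0 + t.height, t.x0 : t.x0 + t.width].copy()) for t in tiles
    ]
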