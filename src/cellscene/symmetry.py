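"""Point-group operators and symmetry expansion of an asymmetric-unit placement.

Supported symbols: ``c<n>`` (cyclic), ``d<n>`` (dihedral), ``t`` (tetrahedral,
12 ops), ``o`` (octahedral, 24), ``i`` (icosahedral, 60).  Orientation
conventions are fixed: the principal axis is +z; for ``d<n>`` the dihedral
2-fold lies along +x; the polyhedral groups are built in the "222" setting
with 2-fold axes along the coordinate axes (for ``t``/``o``, 3-folds along the
cube diagonals; for ``i``, 5-folds along the (0, ±1, ±φ)-type icosahedron
vertex directions).

The polyhedral groups are generated by breadth-first closure from a generator
pair, deduplicating at 1e-8 — self-verifying rather than hard-coded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .coords import Rz, Transform3D, rotation_about_axis

__all__ = ["UnsupportedSymmetryError", "SymmetryGroup", "symmetry_operators", "expand_asymmetric_unit"]

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0
_DEDUP_TOL = 1e-8


class UnsupportedSymmetryError(ValueError):
    """Symmetry symbol outside the supported set."""


@dataclass(frozen=True)
class SymmetryGroup:
    """A point group as an explicit list of proper rotation operators."""

    symbol: str
    operators: tuple[np.ndarray, ...]

    def __len__(self) -> int:
        return len(self.operators)

    def __iter__(self):
        return iter(self.operators)


def _closure(generators: list[np.ndarray], max_size: int = 120) -> list[np.ndarray]:
    """Breadth-first group closure with dedup at ``_DEDUP_TOL``."""
    ops: list[np.ndarray] = [np.eye(3)]

    def seen(M: np.ndarray) -> bool:
        return any(np.max(np.abs(M - G)) < _DEDUP_TOL for G in ops)

    frontier = [np.eye(3)]
    while frontier:
        nxt = []
        for A in frontier:
            for g in generators:
                M = g @ A
                if not seen(M):
                    ops.append(M)
                    nxt.append(M)
                    if len(ops) > max_size:
                        raise RuntimeError("group closure did not terminate (bad generators)")
        frontier = nxt
    return ops


def symmetry_operators(symbol: str) -> SymmetryGroup:
    """Build the operator list for a point-group symbol (case-insensitive)."""
    sym = symbol.strip().lower()
    m = re.fullmatch(r"([cd])(\d+)", sym)
    if m:
        kind, n = m.group(1), int(m.group(2))
        if n < 1:
            raise UnsupportedSymmetryError(f"order must be >= 1 in {symbol!r}")
        cyc = [Rz(360.0 * k / n) for k in range(n)]
        if kind == "c":
            ops = cyc
        else:
            flip = rotation_about_axis([1.0, 0.0, 0.0], 180.0)
            ops = cyc + [flip @ G for G in cyc]
    elif sym == "t":
        ops = _closure([Rz(180.0), rotation_about_axis([1, 1, 1], 120.0)])
    elif sym == "o":
        ops = _closure([Rz(90.0), rotation_about_axis([1, 1, 1], 120.0)])
    elif sym == "i":
        ops = _closure([Rz(180.0), rotation_about_axis([0.0, 1.0, _GOLDEN], 72.0)])
    else:
        raise UnsupportedSymmetryError(f"unknown symmetry symbol {symbol!r}")
    group = SymmetryGroup(sym, tuple(np.ascontiguousarray(G) for G in ops))
    _check_group(group)
    return group


_EXPECTED = {"t": 12, "o": 24, "i": 60}


def _check_group(group: SymmetryGroup) -> None:
    n = len(group)
    if group.symbol in _EXPECTED and n != _EXPECTED[group.symbol]:
        raise RuntimeError(f"{group.symbol}: closure produced {n} operators")
    for G in group:
        if np.max(np.abs(G.T @ G - np.eye(3))) > 1e-9 or np.linalg.det(G) < 0:
            raise RuntimeError(f"{group.symbol}: non-rotation operator")


def expand_asymmetric_unit(placement: Transform3D, group: SymmetryGroup) -> list[Transform3D]:
    """Replicate one asymmetric-unit placement under every group operator.

    Expansion acts about the origin of the placement's source frame:
    ``(G @ R, G @ t)`` for each operator G, in operator order.
    """
    return [
        Transform3D(G @ placement.rotation, G @ placement.translation) for G in group
    ]
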