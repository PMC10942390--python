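"""Deterministic generators for synthetic test inputs — no downloads.

Everything the toolkit consumes (toy atomic structures, particle refinement
records with known ground truth, analytic filament paths, a membrane scene
description) can be generated here from a seed.  Identical parameters and
seed give byte-identical file output.

Scales mimic the systems the toolkit targets: C-alpha-like 3.8 Å walk steps
for structures, tomogram-sized voxel grids for particles, and a ~500 nm
"minicell" (sphere radius 2500 Å) for the surface scene, so tests exercise
realistic magnitudes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .coords import EngineTransform, TomogramFrame, Transform3D
from .structio import Atom, Chain, ParticleRecord, Path3D, Structure

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "make_toy_structure",
    "make_toy_particles",
    "make_helical_path",
    "make_toy_surface_scene",
]

#: 3.8 Å C-alpha step split 3-4-5 style so every component is exact at two
#: decimals — PDB text (3 decimals) then round-trips bit-identically.
_STEP_LEGS = (2.28, 3.04, 0.0)
_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic input: kind, kind-specific params, seed."""

    kind: str  # toy_structure | toy_particles | helical_path | toy_surface_scene
    params: dict = field(default_factory=dict)
    seed: int = 0


def make_fixture(spec: FixtureSpec):
    """Dispatch a :class:`FixtureSpec` to its generator."""
    makers = {
        "toy_structure": make_toy_structure,
        "toy_particles": make_toy_particles,
        "helical_path": make_helical_path,
        "toy_surface_scene": make_toy_surface_scene,
    }
    if spec.kind not in makers:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    if spec.kind == "toy_surface_scene":
        return makers[spec.kind](**spec.params)
    return makers[spec.kind](**spec.params, seed=spec.seed)


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

def make_toy_structure(
    n_chains: int, atoms_per_chain: int, seed: int = 0
) -> tuple[Structure, str]:
    """Random-walk toy structure plus its PDB text rendering.

    Chains are labelled A, B, ...; atoms follow a seeded random walk with
    exact 3.8 Å steps (random signed axis permutations of a 2.28/3.04 leg
    pair), carbon atoms throughout.  Chain starting points are spaced 20 Å
    apart on z so chains do not interleave.
    """
    if n_chains < 1 or atoms_per_chain < 1:
        raise ValueError("need n_chains >= 1 and atoms_per_chain >= 1")
    if n_chains > len(_CHAIN_IDS):
        raise ValueError(f"at most {len(_CHAIN_IDS)} chains supported")
    rng = np.random.default_rng(seed)
    chains = []
    pdb_lines = []
    serial = 1
    for ci in range(n_chains):
        pos = np.array([0.0, 0.0, 20.0 * ci])
        atoms = []
        for ai in range(atoms_per_chain):
            if ai > 0:
                legs = rng.permutation(np.array(_STEP_LEGS))
                signs = rng.choice([-1.0, 1.0], size=3)
                # re-quantize so coordinates equal their 3-decimal PDB rendering
                pos = np.round(pos + signs * legs, 3)
            atoms.append(Atom("C", pos.copy(), 6.0))
            pdb_lines.append(
                f"ATOM  {serial:5d}  CA  ALA {_CHAIN_IDS[ci]}{ai + 1:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00           C"
            )
            serial += 1
        chains.append(Chain(_CHAIN_IDS[ci], tuple(atoms)))
        pdb_lines.append("TER")
    pdb_lines.append("END")
    return Structure(tuple(chains)), "\n".join(pdb_lines) + "\n"


# ---------------------------------------------------------------------------
# toy particles with ground truth
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q, scalar_first=True).as_matrix()


def make_toy_particles(
    n: int, frame: TomogramFrame, seed: int = 0, identity_first: bool = False
) -> tuple[str, list[EngineTransform]]:
    """Particle JSON plus independently computed engine-frame ground truth.

    Records get seeded random voxel centers (inside the central 60% of the
    tomogram) and uniform random alignment rotations.  The ground truth is
    computed brute-force through 4x4 homogeneous matrices and scipy's own
    ZYX Euler decomposition — a route fully independent of the coords module —
    for parameter-recovery tests.  ``identity_first`` pins record 0 to the
    identity alignment at the tomogram center.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    dims, apix, ws = frame.dims, frame.apix, frame.world_scale
    mirror = np.diag([1.0, -1.0, 1.0])
    M4 = np.eye(4)
    M4[:3, :3] = mirror

    records = []
    truths = []
    for i in range(n):
        if identity_first and i == 0:
            center = dims / 2.0
            R = np.eye(3)
        else:
            center = dims * rng.uniform(0.2, 0.8, size=3)
            R = _random_rotation(rng)
        t_src = apix * (center - dims / 2.0)
        records.append(
            {
                "particle_id": f"p{i:04d}",
                "tomogram_id": "toy_tomo",
                "center_voxel": [float(x) for x in center],
                "matrix": [
                    float(v)
                    for v in np.hstack([R, np.zeros((3, 1))]).ravel()
                ],
                "class_label": "toy",
            }
        )
        # brute-force homogeneous chain: mirror . inverse-alignment . mirror
        H = np.eye(4)
        H[:3, :3] = R
        H_eng = M4 @ np.linalg.inv(H) @ M4
        yaw, pitch, roll = Rotation.from_matrix(H_eng[:3, :3]).as_euler("ZYX", degrees=True)
        loc = ws * mirror @ t_src
        truths.append(EngineTransform(loc, (roll, pitch, yaw), ws))
    return json.dumps(records, indent=1), truths


# ---------------------------------------------------------------------------
# analytic filament paths
# ---------------------------------------------------------------------------

def make_helical_path(
    kind: str, params: dict, n_points: int, seed: int = 0
) -> tuple[Path3D, str, str]:
    """Analytic path plus its text and C-alpha PDB renderings.

    kinds: ``line`` (params: length), ``arc`` (radius, angle_deg),
    ``helix`` (radius, pitch, turns).  The path is sampled uniformly in
    parameter; both file renderings are rounded to 3 decimals (PDB precision)
    so the two dialects re-read to identical points.
    """
    if n_points < 2:
        raise ValueError("need n_points >= 2")
    t = np.linspace(0.0, 1.0, n_points)
    if kind == "line":
        L = params["length"]
        pts = np.column_stack([np.zeros(n_points), np.zeros(n_points), L * t])
    elif kind == "arc":
        r = params["radius"]
        ang = np.deg2rad(params["angle_deg"]) * t
        pts = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n_points)])
    elif kind == "helix":
        r, pitch, turns = params["radius"], params["pitch"], params["turns"]
        ang = 2 * np.pi * turns * t
        pts = np.column_stack([r * np.cos(ang), r * np.sin(ang), pitch * turns * t])
    else:
        raise ValueError(f"unknown path kind {kind!r}")
    path = Path3D(pts)

    rounded = np.round(pts, 3)
    text = "\n".join(f"{p[0]:.3f} {p[1]:.3f} {p[2]:.3f}" for p in rounded) + "\n"
    pdb = (
        "\n".join(
            f"ATOM  {i + 1:5d}  CA  ALA A{i + 1:4d}    "
            f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00           C"
            for i, p in enumerate(rounded)
        )
        + "\nEND\n"
    )
    return path, text, pdb


# ---------------------------------------------------------------------------
# membrane scene description
# ---------------------------------------------------------------------------

def make_toy_surface_scene(
    radius: float = 2500.0, patch_edge: float = 50.0, thickness: float = 40.0
) -> dict:
    """Membrane scene config for a minicell-sized spherical envelope.

    Default radius 2500 Å (~500 nm diameter cell); patch edge and bilayer
    thickness at typical lipid-patch scales.  The returned dict is the
    membrane-CLI config schema.
    """
    return {
        "surface": {"kind": "sphere", "params": {"radius": radius}},
        "patch_edge": patch_edge,
        "thickness": thickness,
        "lipid_mesh_id": "lipid_patch",
    }
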