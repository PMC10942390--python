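"""Readers and writers for every external format the toolkit touches.

Formats: PDB / mmCIF atomic models (via gemmi), particle refinement records
(JSON), filament paths (whitespace text or C-alpha PDB traces), the scene
manifest (JSON) and triangle meshes (OBJ text, GLB binary glTF via trimesh).

Particle record schema (one JSON list, order-preserving)::

    {
      "particle_id":  "p0001",
      "tomogram_id":  "tomo_01",
      "center_voxel": [x, y, z],              # voxels
      "matrix":       [r00 r01 r02 tx  ...],  # 3x4 row-major, OR
      "euler":        {"az": .., "alt": .., "phi": ..,
                       "tx": 0, "ty": 0, "tz": 0},
      "class_label":  "ribosome",             # optional
      "score":        1.23                    # optional
    }

Both alignment forms yield identical :class:`~cellscene.coords.Transform3D`
for equivalent parameters.  An import shim for one observed EMAN2 per-particle
JSON layout (``coord`` + ``xform.align3d``) is available behind
``eman2_layout=True``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .coords import InvalidRotationError, Transform3D, euler_to_rotation

__all__ = [
    "FormatError",
    "EmptyInputError",
    "SchemaError",
    "PathParseError",
    "TooShortError",
    "ManifestVersionError",
    "ManifestValidationError",
    "Atom",
    "Chain",
    "Structure",
    "ParticleRecord",
    "Path3D",
    "read_structure",
    "read_particle_params",
    "write_particle_params",
    "read_path",
    "read_scene_manifest",
    "write_scene_manifest",
    "write_mesh",
]

SCHEMA_VERSION = "1.0"


class FormatError(ValueError):
    """A file could not be parsed in its declared format."""


class EmptyInputError(ValueError):
    """A file parsed fine but contained no usable content."""


class SchemaError(ValueError):
    """A JSON document is missing a required key or has a malformed value."""


class PathParseError(ValueError):
    """A path text line is malformed."""


class TooShortError(ValueError):
    """A path has fewer than two points."""


class ManifestVersionError(ValueError):
    """Unknown scene-manifest schema version."""


class ManifestValidationError(ValueError):
    """A scene manifest violates referential integrity."""


# ---------------------------------------------------------------------------
# atomic structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    element: str
    position: np.ndarray  # (3,) Å
    weight: float  # scattering-mass proxy (atomic number)


@dataclass(frozen=True)
class Chain:
    chain_id: str
    atoms: tuple[Atom, ...]


@dataclass(frozen=True)
class Structure:
    """Ordered chains of atoms, coordinates in Å."""

    chains: tuple[Chain, ...]

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids: {ids}")
        for c in self.chains:
            if not c.atoms:
                raise ValueError(f"chain {c.chain_id!r} is empty")
            for a in c.atoms:
                if not np.all(np.isfinite(a.position)):
                    raise ValueError(f"non-finite atom position in chain {c.chain_id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def coordinates(self) -> np.ndarray:
        """All atom positions, (N, 3), chains concatenated in order."""
        return np.array([a.position for c in self.chains for a in c.atoms])


def read_structure(path: str | Path, include_hetero: bool = False) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Chains follow file order, coordinates are in Å.  Hetero/solvent atoms are
    excluded unless ``include_hetero``; of alternate locations only ``A`` (or
    blank) is kept so each atom has exactly one position.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as e:
        raise FormatError(f"could not parse {path.name}: {e}") from e
    if len(st) == 0:
        raise EmptyInputError(f"{path.name}: no models")
    chains: list[Chain] = []
    for ch in st[0]:
        atoms: list[Atom] = []
        for res in ch:
            if not include_hetero and res.het_flag == "H":
                continue
            for at in res:
                if at.altloc not in ("", "\0", "A"):
                    continue
                pos = np.array([at.pos.x, at.pos.y, at.pos.z])
                atoms.append(Atom(at.element.name, pos, float(at.element.atomic_number)))
        if atoms:
            chains.append(Chain(ch.name, tuple(atoms)))
    if not chains:
        raise EmptyInputError(f"{path.name}: no atoms after filtering (hetero excluded)")
    return Structure(tuple(chains))


# ---------------------------------------------------------------------------
# particle refinement records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticleRecord:
    """One subtomogram-averaging particle: position, alignment, class."""

    particle_id: str
    tomogram_id: str
    center_voxel: np.ndarray  # (3,) voxels
    alignment: Transform3D  # particle -> reference alignment
    class_label: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "center_voxel", np.asarray(self.center_voxel, dtype=float).reshape(3)
        )


def _require(rec: dict, key: str, index: int):
    if key not in rec:
        raise SchemaError(f"record {index}: missing required key {key!r}")
    return rec[key]


def _alignment_from_matrix(flat: Sequence[float], index: int) -> Transform3D:
    m = np.asarray(flat, dtype=float)
    if m.shape != (12,):
        raise SchemaError(f"record {index}: 'matrix' must be 12 numbers (3x4 row-major)")
    m = m.reshape(3, 4)
    R, t = m[:, :3], m[:, 3]
    err = np.max(np.abs(R.T @ R - np.eye(3)))
    if err > 1e-4 or np.linalg.det(R) < 0:
        raise InvalidRotationError(
            f"record {index}: alignment matrix not a rotation (|R^T R - I|_inf = {err:.3g})"
        )
    # project onto SO(3) so downstream invariants hold at 1e-9
    U, _, Vt = np.linalg.svd(R)
    return Transform3D(U @ Vt, t)


def _alignment_from_euler(e: dict, index: int) -> Transform3D:
    for key in ("az", "alt", "phi"):
        if key not in e:
            raise SchemaError(f"record {index}: euler form missing key {key!r}")
    R = euler_to_rotation(e["az"], e["alt"], e["phi"])
    t = np.array([e.get("tx", 0.0), e.get("ty", 0.0), e.get("tz", 0.0)], dtype=float)
    return Transform3D(R, t)


def read_particle_params(path: str | Path, eman2_layout: bool = False) -> list[ParticleRecord]:
    """Read particle refinement records from JSON, order preserved."""
    with open(path) as fh:
        data = json.load(fh)
    if eman2_layout:
        data = [_from_eman2_record(rec, i) for i, rec in enumerate(data)]
    if not isinstance(data, list):
        raise SchemaError("particle file must be a JSON list of records")
    records = []
    for i, rec in enumerate(data):
        pid = str(_require(rec, "particle_id", i))
        tid = str(_require(rec, "tomogram_id", i))
        cv = np.asarray(_require(rec, "center_voxel", i), dtype=float)
        if cv.shape != (3,):
            raise SchemaError(f"record {i}: 'center_voxel' must be a 3-vector")
        if "matrix" in rec:
            alignment = _alignment_from_matrix(rec["matrix"], i)
        elif "euler" in rec:
            alignment = _alignment_from_euler(rec["euler"], i)
        else:
            raise SchemaError(f"record {i}: missing required key 'matrix' or 'euler'")
        records.append(
            ParticleRecord(
                pid, tid, cv, alignment,
                class_label=str(rec.get("class_label", "")),
                score=rec.get("score"),
            )
        )
    return records


def _from_eman2_record(rec: dict, i: int) -> dict:
    """Map one observed EMAN2 per-particle layout onto the native schema."""
    out = {
        "particle_id": rec.get("particle_id", f"ptcl_{i:05d}"),
        "tomogram_id": rec.get("tomogram_id", rec.get("src", "tomogram")),
        "center_voxel": rec.get("coord", rec.get("center_voxel")),
    }
    if out["center_voxel"] is None:
        raise SchemaError(f"record {i}: EMAN2 layout missing 'coord'")
    xf = rec.get("xform.align3d")
    if xf is None or "matrix" not in xf:
        raise SchemaError(f"record {i}: EMAN2 layout missing 'xform.align3d'")
    out["matrix"] = xf["matrix"]
    if "class" in rec:
        out["class_label"] = str(rec["class"])
    if "score" in rec:
        out["score"] = rec["score"]
    return out


def write_particle_params(records: Iterable[ParticleRecord], path: str | Path) -> None:
    """Write records in the native JSON schema (matrix form)."""
    out = []
    for r in records:
        m = np.hstack([r.alignment.rotation, r.alignment.translation[:, None]])
        rec = {
            "particle_id": r.particle_id,
            "tomogram_id": r.tomogram_id,
            "center_voxel": list(r.center_voxel),
            "matrix": [float(x) for x in m.ravel()],
            "class_label": r.class_label,
        }
        if r.score is not None:
            rec["score"] = r.score
        out.append(rec)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)


# ---------------------------------------------------------------------------
# filament paths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Path3D:
    """Ordered polyline in Å; ``closed`` marks a loop (last joins first)."""

    points: np.ndarray  # (N, 3)
    closed: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError(f"path needs an (N>=2, 3) point array, got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("path points must be finite")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps <= 1e-6):
            raise ValueError("consecutive path points closer than 1e-6 Å")
        object.__setattr__(self, "points", pts)

    def length(self) -> float:
        pts = self.points
        L = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        if self.closed:
            L += float(np.linalg.norm(pts[0] - pts[-1]))
        return L


def read_path(path: str | Path, dialect: str = "text") -> Path3D:
    """Read a filament path.

    ``text``: one whitespace-separated ``x y z`` triplet per line (Å), blank
    lines and ``#`` comments ignored.  ``calpha``: a PDB file whose CA atoms,
    in residue order, define the path; all other atoms are ignored.
    """
    path = Path(path)
    if dialect == "text":
        points = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            fields = s.split()
            if len(fields) != 3:
                raise PathParseError(f"{path.name}, line {lineno}: expected 3 fields, got {len(fields)}")
            try:
                points.append([float(x) for x in fields])
            except ValueError:
                raise PathParseError(f"{path.name}, line {lineno}: non-numeric field") from None
    elif dialect == "calpha":
        try:
            st = gemmi.read_structure(str(path))
        except (RuntimeError, ValueError) as e:
            raise FormatError(f"could not parse {path.name}: {e}") from e
        points = []
        for ch in st[0]:
            for res in ch:
                for at in res:
                    if at.name == "CA" and at.altloc in ("", "\0", "A"):
                        points.append([at.pos.x, at.pos.y, at.pos.z])
    else:
        raise ValueError(f"unknown path dialect {dialect!r} (expected 'text' or 'calpha')")
    if len(points) < 2:
        raise TooShortError(f"{path.name}: a path needs >= 2 points, got {len(points)}")
    return Path3D(np.asarray(points, dtype=float))


# ---------------------------------------------------------------------------
# scene manifest
# ---------------------------------------------------------------------------

def write_scene_manifest(scene, path: str | Path) -> None:
    """Serialize a :class:`~cellscene.scene.SceneManifest` to JSON.

    Validates referential integrity (mesh ids, annotation keys) before
    writing; round trips field-for-field with :func:`read_scene_manifest`.
    """
    scene.validate()
    doc = {
        "schema_version": SCHEMA_VERSION,
        "meshes": {k: dict(v) for k, v in scene.meshes.items()},
        "instances": [
            {
                "instance_id": i.instance_id,
                "mesh_id": i.mesh_id,
                "location": [float(x) for x in i.transform.location],
                "rotator": [float(a) for a in i.transform.rotator],
                "scale": float(i.transform.scale),
                "annotation_key": i.annotation_key,
                "bounding_radius": float(i.bounding_radius),
            }
            for i in scene.instances
        ],
        "annotations": {
            k: {"name": e.name, "description": e.description,
                "source_accession": e.source_accession}
            for k, e in scene.annotations.entries.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_scene_manifest(path: str | Path):
    from .scene import AnnotationEntry, AnnotationTable, SceneInstance, SceneManifest
    from .coords import EngineTransform

    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ManifestVersionError(f"unknown scene-manifest schema version {version!r}")
    annotations = AnnotationTable(
        {k: AnnotationEntry(e["name"], e["description"], e.get("source_accession", ""))
         for k, e in doc.get("annotations", {}).items()}
    )
    instances = [
        SceneInstance(
            instance_id=i["instance_id"],
            mesh_id=i["mesh_id"],
            transform=EngineTransform(
                np.asarray(i["location"], dtype=float),
                tuple(i["rotator"]),
                i.get("scale", 1.0),
            ),
            annotation_key=i.get("annotation_key", ""),
            bounding_radius=i.get("bounding_radius", 0.0),
        )
        for i in doc.get("instances", [])
    ]
    scene = SceneManifest(
        meshes={k: dict(v) for k, v in doc.get("meshes", {}).items()},
        instances=instances,
        annotations=annotations,
    )
    try:
        scene.validate()
    except ValueError as e:
        raise ManifestValidationError(str(e)) from e
    return scene


# ---------------------------------------------------------------------------
# mesh export
# ---------------------------------------------------------------------------

def write_mesh(mesh, path: str | Path, format: str | None = None) -> None:
    """Write a :class:`~cellscene.meshgen.TriMesh` as OBJ text or binary GLB.

    OBJ output carries one ``v`` line per vertex and one ``f`` line per
    triangle with 1-based indices.  GLB is a binary glTF container with a
    single mesh primitive, written through trimesh.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if len(mesh.vertices) == 0 or len(mesh.triangles) == 0:
        raise EmptyInputError("refusing to write an empty mesh")
    if format == "obj":
        lines = [f"# cellscene mesh {mesh.label!r}".replace("'", "")]
        lines += [f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}" for v in mesh.vertices]
        lines += [f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}" for t in mesh.triangles]
        path.write_text("\n".join(lines) + "\n")
    elif format == "glb":
        import trimesh

        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
        tm.export(str(path), file_type="glb")
    else:
        raise ValueError(f"unknown mesh format {format!r} (expected 'obj' or 'glb')")
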