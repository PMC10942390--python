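"""Scene assembly, annotation, picking, and simple protein motion.

This module turns refined particle records, scatter requests, and
source-frame placements (filaments, membranes) into engine-frame
:class:`SceneInstance` records collected in a :class:`SceneManifest` — the
JSON hand-off a game-engine import script consumes.  It also provides
engine-independent geometric analogues of the in-game interactions: ray
picking of the first visible object (bounding-sphere line trace), destroying
a picked instance to "peel open" a complex, annotation lookup from a JSON
dictionary, and a reflecting tilt-oscillation trajectory for displaying
rigid-body protein motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coords import (
    EngineTransform,
    Placement,
    TomogramFrame,
    Transform3D,
    flip_handedness,
    invert,
    rotation_to_rotator,
    tomo_to_engine_position,
)
from .structio import ParticleRecord
from .symmetry import SymmetryGroup, expand_asymmetric_unit

__all__ = [
    "MappingError",
    "PackingError",
    "InvalidRayError",
    "NotFoundError",
    "SceneInstance",
    "AnnotationEntry",
    "AnnotationTable",
    "SceneManifest",
    "TiltState",
    "engine_transform_from_source",
    "placements_to_instances",
    "particles_to_instances",
    "scatter_instances",
    "pick_first",
    "destroy",
    "lookup",
    "tilt_trajectory",
]


class MappingError(KeyError):
    """A particle class label has no mesh assigned."""


class PackingError(RuntimeError):
    """Scatter placement could not satisfy the clearance constraint."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"placed only {achieved} of {requested} instances within the attempt budget"
        )


class InvalidRayError(ValueError):
    """Pick ray has zero direction."""


class NotFoundError(KeyError):
    """Instance id or annotation key not present."""


@dataclass(frozen=True)
class SceneInstance:
    """One placed mesh: engine transform plus annotation key."""

    instance_id: str
    mesh_id: str
    transform: EngineTransform
    annotation_key: str = ""
    bounding_radius: float = 0.0

    def __post_init__(self) -> None:
        if self.bounding_radius < 0:
            raise ValueError(f"bounding_radius must be >= 0, got {self.bounding_radius}")


@dataclass(frozen=True)
class AnnotationEntry:
    name: str
    description: str
    source_accession: str = ""


@dataclass(frozen=True)
class AnnotationTable:
    """JSON-dictionary annotation database: key -> (name, description, accession)."""

    entries: dict[str, AnnotationEntry] = field(default_factory=dict)


@dataclass
class SceneManifest:
    """The full scene: mesh table, placed instances, annotation table."""

    meshes: dict[str, dict] = field(default_factory=dict)
    instances: list[SceneInstance] = field(default_factory=list)
    annotations: AnnotationTable = field(default_factory=AnnotationTable)

    def validate(self) -> None:
        ids = [i.instance_id for i in self.instances]
        if len(set(ids)) != len(ids):
            dupes = sorted({x for x in ids if ids.count(x) > 1})
            raise ValueError(f"duplicate instance ids: {dupes}")
        for i in self.instances:
            if i.mesh_id not in self.meshes:
                raise ValueError(
                    f"instance {i.instance_id!r} references absent mesh {i.mesh_id!r}"
                )
            if i.annotation_key and i.annotation_key not in self.annotations.entries:
                raise ValueError(
                    f"instance {i.instance_id!r} references absent annotation "
                    f"{i.annotation_key!r}"
                )


@dataclass(frozen=True)
class TiltState:
    """Instantaneous state of a tilt oscillation about a fixed random axis."""

    axis: np.ndarray
    angle: float
    max_angle: float
    rate: float
    direction: int

    def __post_init__(self) -> None:
        ax = np.asarray(self.axis, dtype=float).reshape(3)
        if abs(np.linalg.norm(ax) - 1.0) > 1e-9:
            raise ValueError("tilt axis must be a unit vector")
        if abs(self.angle) > self.max_angle + 1e-9:
            raise ValueError(f"|angle| {abs(self.angle)} exceeds max_angle {self.max_angle}")
        object.__setattr__(self, "axis", ax)


# ---------------------------------------------------------------------------
# source frame -> engine instances
# ---------------------------------------------------------------------------

def engine_transform_from_source(
    t: Transform3D, world_scale: float = 1.0, mirror_axis: str = "y", scale: float | None = None
) -> EngineTransform:
    """Convert a source-frame (Å, right-handed) rigid transform to the engine.

    Rotation is conjugated by the axis mirror; the translation has the mirror
    and ``world_scale`` (engine units per Å) applied.  ``scale`` defaults to
    ``world_scale`` so meshes exported in Å keep their proportions.
    """
    i = "xyz".index(mirror_axis)
    d = np.ones(3)
    d[i] = -1.0
    rotator = rotation_to_rotator(flip_handedness(t.rotation, mirror_axis))
    return EngineTransform(
        world_scale * d * t.translation, rotator, world_scale if scale is None else scale
    )


def placements_to_instances(
    placements: list[Placement],
    prefix: str,
    world_scale: float = 1.0,
    mirror_axis: str = "y",
    annotation_key: str = "",
    bounding_radius: float = 0.0,
) -> list[SceneInstance]:
    """Wrap source-frame placements (filament segments, lipid leaflets) as
    engine instances with sequential ids ``<prefix>/<k>``."""
    return [
        SceneInstance(
            f"{prefix}/{k}",
            p.mesh_id,
            engine_transform_from_source(p.transform, world_scale, mirror_axis),
            annotation_key,
            bounding_radius,
        )
        for k, p in enumerate(placements)
    ]


def particles_to_instances(
    records: list[ParticleRecord],
    frame: TomogramFrame,
    mesh_map: dict[str, str],
    sym: SymmetryGroup | None = None,
    mirror_axis: str = "y",
    bounding_radius: float = 0.0,
) -> list[SceneInstance]:
    """Map refined particles back into the scene, one instance per particle.

    The stored alignment takes the particle to the reference, so the placed
    reference model gets the INVERSE alignment rotation; position is the
    voxel-center chain through :func:`tomo_to_engine_position`.  With ``sym``,
    each record expands to |G| instances (expansion about the tomogram origin
    in the source frame, record order then operator order).
    """
    instances = []
    for rec in records:
        if rec.class_label not in mesh_map:
            raise MappingError(
                f"particle {rec.particle_id!r}: class label {rec.class_label!r} "
                f"has no mesh in the mesh map"
            )
        mesh_id = mesh_map[rec.class_label]
        t_src = frame.apix * (rec.center_voxel - frame.dims / 2.0)
        placement = Transform3D(invert(rec.alignment).rotation, t_src)
        expanded = (
            expand_asymmetric_unit(placement, sym) if sym is not None else [placement]
        )
        for k, p in enumerate(expanded):
            iid = rec.particle_id if len(expanded) == 1 else f"{rec.particle_id}/sym{k}"
            instances.append(
                SceneInstance(
                    iid,
                    mesh_id,
                    engine_transform_from_source(p, frame.world_scale, mirror_axis),
                    annotation_key=rec.class_label,
                    bounding_radius=bounding_radius,
                )
            )
    return instances


# ---------------------------------------------------------------------------
# random scatter
# ---------------------------------------------------------------------------

def _random_rotator(rng: np.random.Generator) -> tuple[float, float, float]:
    """Uniform random rotation expressed as an engine rotator."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rotation_to_rotator(R)


def scatter_instances(
    mesh_id: str,
    n: int,
    region: tuple[np.ndarray, np.ndarray],
    min_clearance: float = 0.0,
    seed: int = 0,
    prefix: str | None = None,
    bounding_radius: float = 0.0,
    annotation_key: str = "",
) -> list[SceneInstance]:
    """Scatter ``n`` copies uniformly in an axis-aligned box (engine units).

    Positions are rejection-sampled so all pairwise center distances are
    >= ``min_clearance``, with a 100·n candidate budget; orientations are
    uniform random.  Identical seeds give identical output.  Raises
    :class:`PackingError` (reporting the achieved count) when the budget runs
    out.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    lo = np.asarray(region[0], dtype=float).reshape(3)
    hi = np.asarray(region[1], dtype=float).reshape(3)
    if np.any(hi <= lo):
        raise ValueError(f"region must be a nonempty box, got {lo} .. {hi}")
    rng = np.random.default_rng(seed)
    prefix = prefix or mesh_id
    placed: list[np.ndarray] = []
    instances: list[SceneInstance] = []
    budget = 100 * max(n, 1)
    attempts = 0
    while len(placed) < n:
        if attempts >= budget:
            raise PackingError(n, len(placed))
        attempts += 1
        pos = rng.uniform(lo, hi)
        if min_clearance > 0 and placed:
            d = np.linalg.norm(np.array(placed) - pos, axis=1)
            if np.any(d < min_clearance):
                continue
        placed.append(pos)
        instances.append(
            SceneInstance(
                f"{prefix}/{len(placed) - 1}",
                mesh_id,
                EngineTransform(pos, _random_rotator(rng)),
                annotation_key,
                bounding_radius,
            )
        )
    return instances


# ---------------------------------------------------------------------------
# picking and destruction
# ---------------------------------------------------------------------------

def _ray_sphere_t(origin, direction, center, radius) -> float | None:
    """Smallest positive ray parameter hitting the sphere, or None."""
    oc = center - origin
    b = float(oc @ direction)
    c = float(oc @ oc) - radius * radius
    disc = b * b - c
    if disc < 0:
        return None
    s = np.sqrt(disc)
    for t in (b - s, b + s):
        if t > 0:
            return float(t)
    return None


def pick_first(
    scene: SceneManifest, ray_origin, ray_direction
) -> str | None:
    """First instance hit by the ray — the line-trace 'object at the center of
    the view'.

    Bounding spheres have center = location and radius = bounding_radius ·
    scale.  Returns the instance id with the smallest positive hit parameter
    (ties broken lexicographically), or None.
    """
    d = np.asarray(ray_direction, dtype=float).reshape(3)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise InvalidRayError("ray direction must be nonzero")
    d = d / nd
    o = np.asarray(ray_origin, dtype=float).reshape(3)
    best: tuple[float, str] | None = None
    for inst in scene.instances:
        r = inst.bounding_radius * inst.transform.scale
        if r <= 0:
            continue
        t = _ray_sphere_t(o, d, inst.transform.location, r)
        if t is None:
            continue
        key = (t, inst.instance_id)
        if best is None or key < best:
            best = key
    return None if best is None else best[1]


def destroy(scene: SceneManifest, instance_id: str) -> SceneManifest:
    """Scene with exactly the named instance removed ("shoot" interaction).

    The annotation table and mesh table are untouched.
    """
    kept = [i for i in scene.instances if i.instance_id != instance_id]
    if len(kept) == len(scene.instances):
        raise NotFoundError(f"no instance with id {instance_id!r}")
    return SceneManifest(scene.meshes, kept, scene.annotations)


def lookup(table: AnnotationTable, key: str) -> AnnotationEntry:
    """Annotation entry for a key (the on-screen description source)."""
    try:
        return table.entries[key]
    except KeyError:
        raise NotFoundError(f"no annotation entry for key {key!r}") from None


# ---------------------------------------------------------------------------
# tilt oscillation
# ---------------------------------------------------------------------------

def tilt_trajectory(
    max_angle: float,
    rate: float,
    duration: float,
    dt: float,
    seed: int = 0,
) -> list[tuple[float, TiltState]]:
    """Reflecting tilt oscillation about a random fixed axis.

    The angle advances by ±rate·dt per step; the direction inverts exactly
    when the next step would exceed ``max_angle`` in magnitude, so
    |angle| <= max_angle throughout.  The axis is drawn once per trajectory
    from the seeded uniform sphere distribution.
    """
    for name, v in (("max_angle", max_angle), ("rate", rate), ("dt", dt)):
        if not (v > 0):
            raise ValueError(f"{name} must be > 0, got {v}")
    if duration < 0:
        raise ValueError(f"duration must be >= 0, got {duration}")
    if rate * dt > max_angle:
        raise ValueError(
            f"one step (rate*dt = {rate * dt:.3g}°) exceeds max_angle {max_angle}°; "
            "the reflecting bound cannot be honoured"
        )
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle, direction = 0.0, 1
    out = [(0.0, TiltState(axis, angle, max_angle, rate, direction))]
    n_steps = int(round(duration / dt))
    for k in range(1, n_steps + 1):
        step = rate * dt
        if abs(angle + direction * step) > max_angle + 1e-12:
            direction = -direction
        angle += direction * step
        out.append((k * dt, TiltState(axis, angle, max_angle, rate, direction)))
    return out
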