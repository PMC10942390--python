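# Methods

This note documents the geometric models, conventions, numerical choices and
known limitations of `cellscene`, and what the synthetic-data generators do
and do not emulate.

## Coordinate conventions

The toolkit distinguishes two frames. The **source frame** is right-handed
with coordinates in ångströms; tomogram particle positions enter it as
`apix · (center_voxel − dims/2)`, i.e. the tomogram center is the origin.
The **engine frame** is left-handed and Z-up, with positions in engine units
(`world_scale` engine units per Å, default 1) and rotations as a
(roll, pitch, yaw) rotator in degrees, each normalized to (−180, 180].

* **Euler triplets.** Refinement orientations (az, alt, phi) compose as
  intrinsic ZXZ: `R = Rz(az)·Rx(alt)·Rz(phi)`. This matches the common
  subtomogram-refinement convention and is verified structurally in tests
  against explicit matrix products and an independent Euler library.
* **Handedness.** The right→left-handed conversion conjugates by a single
  axis mirror, `M·R·M` with `M = diag(1,−1,1)`; mirroring one axis suffices
  and Y is the conventional screen-versus-world flip. The mirror axis is
  configurable. The operation is an involution and preserves det = +1.
* **Rotator.** The engine rotator composes as `Yaw(z)·Pitch(y)·Roll(x)`
  with pitch restricted to [−90°, 90°]; at |pitch| = 90° (gimbal lock) only
  yaw − sign(pitch)·roll is determined, and the tie-break stores it all in
  yaw with roll = 0. Engine vendors differ in rotator sign conventions; this
  contract is self-consistent (exact round trip at 1e−9 over random
  rotations) but has not been validated against any particular engine build,
  which is why both the mirror axis and the decomposition sit behind one
  module boundary.
* **Mapping-back.** A refinement alignment takes the particle to the
  reference, so placing the reference model at the particle uses the
  **inverse** alignment rotation. Alignment matrices read from JSON are
  accepted at an orthonormality tolerance of 1e−4 (measurement noise) and
  projected onto SO(3) by SVD so all downstream invariants hold at 1e−9.

Whether particle centers are stored in binned or unbinned voxels is
dataset-dependent; `apix` is therefore always explicit, never guessed.

## Symmetry

Point groups are explicit operator lists: cyclic and dihedral groups by
construction (principal axis +z, dihedral 2-fold along +x), tetrahedral /
octahedral / icosahedral groups by breadth-first closure from a generator
pair, deduplicating at 1e−8. The icosahedral group is built in the "222"
setting (2-folds on the coordinate axes) from Rz(180°) and a 72° rotation
about the (0, 1, φ) vertex axis; closure is self-verifying — the constructor
checks the expected orders (12/24/60) and operator properness. Expansion of
an asymmetric-unit placement acts about the source-frame origin,
`(G·R, G·t)`; expanding about the molecule's own axis instead can be done by
composing placements before expansion.

## Filament framing

Paths traced from tomograms contain straight runs and inflections, for which
Frenet frames are undefined or flip sign. Frames are therefore computed with
the **double-reflection rotation-minimizing-frame (RMF)** method: each step
reflects the previous frame through the chord bisector plane, then through
the bisector of the reflected and true next tangent. The method is
second-order in the step size (measured self-convergence ratio ≈ 4 when the
step is halved) and contributes no rotation about the tangent, so the helical
twist term `Rz(k·twist)` is the only tangential rotation between segments.

Resampling places samples at arc lengths 0, s, 2s, … ≤ L; the start is always
included and the end only when it lies on the grid within 1e−6 Å — uniform
rise matters more than covering a final partial segment. Tangents are
chord-interpolated (per-vertex means of adjacent segment directions, blended
within segments), so tangent accuracy is set by the input polyline density,
not by the resampling. A path shorter than one rise yields a single segment
and a warning. The default seed normal is the coordinate axis with the
smallest tangent component, orthogonalized — deterministic, so placements
reproduce exactly. Closed paths do not adjust twist by default; a
`close_twist` option rounds the twist so the accumulated twist at closure is
a multiple of 360°.

## Membranes

Membrane shapes are analytic surfaces S(u, v) with outward unit normals
N(u, v): sphere, flat sheet, tube (an RMF-framed path swept with a circle),
and cisterna (a disc with a semicircular toroidal rim, revolved — the basic
Golgi/thylakoid pancake). Tiling aims at near-uniform spacing with no
optimization step: spheres use a deterministic Fibonacci lattice with
`round(4πr²/edge²)` points (nearest-neighbor spacing within [0.7, 1.3]·edge
for ≥95 % of patches); the other kinds use arc-length-corrected grids.
Patch in-plane orientation follows the local u-direction (local east on the
sphere) so neighboring patches vary smoothly.

A **bilayer** duplicates each mid-surface patch into two leaflets at
±thickness/2 along the normal; the inner leaflet is flipped 180° about the
patch's in-plane x axis so lipid headgroups face outward on both sides.
The lipid patch itself is external content — a mesh id with a stated edge
length — keeping geometry decoupled from chemistry. Membrane proteins are
placed with local +z aligned to the surface normal and can optionally clear
all lipid patches within a clearance radius (centers strictly inside are
removed); with clearance 0 proteins simply overlap the lipid, which mirrors
current practice. No seam smoothing or curvature-adaptive patch deformation
is attempted.

Both the filament and membrane modules return **source-frame placements**
(mesh id + rigid transform in Å); `scene.placements_to_instances` applies the
mirror, world scale and rotator decomposition in one place. This keeps the
geometry modules free of engine conventions and makes their outputs directly
checkable against analytic expectations (leaflet radii, twist angles).

## Chain meshes

A "surface at resolution d" is simulated as a sum of isotropic Gaussians,
σ = d/2.355 (FWHM = d), one per non-hydrogen atom, weighted by atomic number
as the scattering-mass proxy. The grid spacing defaults to d/3 (comfortable
Nyquist margin; spacing > d/2 is rejected) and the grid extends 4σ beyond the
atom bounding box, so the truncated Gaussian mass error (~0.1 %) and the
level sets stay inside the grid. The default contour is 20 % of the per-chain
density maximum — scale-free, so congruent chains give congruent meshes.
Surfaces are extracted with marching cubes and degenerate triangles removed.
Each peptide chain is meshed independently and labelled, so chains are
separate placeable/pickable objects. No decimation or level-of-detail is
generated — that is the renderer's virtualized-geometry job. Triangle counts
therefore depend on this pipeline's grid choices and are not comparable to
counts produced by other viewers' surface algorithms.

## Scene interactions

Picking is a bounding-sphere ray test (center = instance location, radius =
bounding radius × scale), returning the smallest positive hit parameter with
lexicographic tie-break — an engine line trace is mesh-accurate, but the
sphere analogue is dependency-free and exhaustively checkable. Scatter
placement rejection-samples uniform positions and orientations with a 100·n
candidate budget and reports the achieved count on failure; identical seeds
give identical scenes. The tilt oscillation advances by ±rate·dt about one
random axis per trajectory and inverts direction exactly when the next step
would exceed the maximum angle; a single step larger than the bound is
rejected as unsatisfiable. Engine-side collision response is not emulated.

## ODS rig

The stereo panorama uses per-tile piecewise-constant ODS: each tile of the
equirectangular grid is rendered by a pinhole camera whose eye offset is
evaluated at the tile's yaw center. True per-column ODS requires renderer
internals; per-tile is what tile-wise rendering pipelines implement, and it
merges nearly seamlessly at the equator while leaving visible vertical seams
near the poles. The eye offset deliberately does not shrink with pitch —
stereo at the poles is geometrically impossible for any horizontal baseline,
so the rig documents rather than hides it. The default working grid is a
6000×3000-pixel frame as 60 tiles on a 10×6 grid (hfov 36°, vfov 30° per
tile); the interpupillary distance is a free parameter in engine units so the
world scale applies. Tile assembly is pure placement, bit-exact, with no
blending.

## Synthetic data

The fixture generators produce every input the tests need, deterministically
under a seed:

* **Toy structures** are random walks with exact 3.8 Å steps (C-alpha-like
  spacing) whose coordinates are quantized to PDB precision, so PDB round
  trips are bit-identical. They have realistic bond geometry statistics but
  no secondary structure, side chains or element diversity.
* **Toy particles** carry uniform random orientations and centers in a
  256×256×128-voxel, 5 Å/voxel tomogram (typical binned CryoET scales), with
  engine-frame ground truth computed through an independent route (4×4
  homogeneous matrices and an external Euler decomposition), so recovery
  tests compare two implementations, not one with itself.
* **Analytic paths** (line, arc, helix) have closed-form geometry so framing
  errors are measurable; the helix default (r = 50 Å, pitch 100 Å, two turns)
  is sampled at 4000 polyline points so path discretization does not mask
  framing error at the ~200-segment scale used in tests.
* The **surface scene** defaults to a sphere of radius 2500 Å — a ~500 nm
  minicell — so membrane tests run at realistic magnitudes.

What passing tests show: the conversions, framings and tilings are correct to
their stated tolerances on inputs whose ground truth is known. What they do
not show: robustness to malformed real-world refinement exports beyond the
documented schema, visual quality of real lipid/protein meshes, or agreement
with any specific engine's rotator conventions.

## Problem sizes

The default verification runs use 100 particles, ~130 symmetry operators
(exhaustive closure over all eight supported groups), 200 filament frames
against a 10×-finer oracle, 1257 sphere patches, a single-Gaussian density
grid at 0.5 Å spacing, and 1000 random picking scenes — sizes chosen so each
suite isolates one error source while the full suite stays interactive.
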