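# cellscene

**From CryoET refinement results to a game-engine-ready scene.**

Cryogenic electron tomography (CryoET) with subtomogram averaging yields, for
each identified macromolecule in a cell, its position in the tomogram (voxels),
its orientation (an alignment transform or az/alt/phi Euler triplet), and its
conformational class. Modern game engines with virtualized-geometry renderers
can draw billions of triangles interactively — enough to show every ribosome,
spike, filament and lipid patch of a cell at atomic resolution — but they speak
a different language: left-handed Z-up coordinates, (roll, pitch, yaw)
rotators in degrees, and instanced static meshes.

`cellscene` is the bridge. It is a renderer-agnostic Python toolkit that

* converts atomic models (PDB/mmCIF) into **per-chain surface meshes** at a
  chosen resolution (Gaussian density simulation + marching cubes; OBJ or
  binary glTF output),
* maps **particle refinement records** back into the scene, handling the Euler
  convention, the inverse-alignment rotation, the voxel→Å→engine-unit chain
  and the right-to-left-handed mirror,
* expands one asymmetric unit under **point-group symmetry** (c*n*, d*n*, t,
  o, i),
* places **helical filament segments** along arbitrary traced paths using
  rotation-minimizing frames plus per-segment twist,
* builds **organelle membranes** by tiling parametric surfaces (sphere, tube,
  sheet, cisterna) with square lipid patches as proper bilayers, and inserts
  membrane proteins,
* assembles everything into a validated JSON **scene manifest** with an
  annotation database, plus engine-independent analogues of the in-game
  interactions (ray picking, destroy, tilt oscillation),
* and emits an **omnidirectional-stereo (ODS) camera rig** — tiled
  equirectangular poses whose eye baseline rotates with the viewing azimuth —
  for producing 3D 360° videos.

## The core conversions

A particle with alignment rotation $R$ (the transform taking the particle to
the averaged reference, convention $R = R_z(az)\,R_x(alt)\,R_z(phi)$) and
center $\mathbf{c}$ (voxels) in a tomogram with voxel size $a$ (Å/voxel) and
dimensions $\mathbf{d}$ becomes an engine instance with

$$
\mathbf{x}_{engine} = s\,M\,a\,(\mathbf{c} - \mathbf{d}/2), \qquad
R_{engine} = M\,R^{-1}\,M,
$$

where $M = \mathrm{diag}(1,-1,1)$ mirrors one axis (right- to left-handed) and
$s$ is the world scale in engine units per Å. $R_{engine}$ is then decomposed
into the engine rotator $R_{engine} = \mathrm{Yaw}(z)\cdot\mathrm{Pitch}(y)\cdot\mathrm{Roll}(x)$.

Filaments are framed with the double-reflection rotation-minimizing-frame
method (well defined on straight runs, no Frenet flips), so segment $k$ of a
helical filament with rise $\rho$ and twist $\tau$ sits at arc length
$k\rho$ with rotation $F_k \cdot R_z(k\tau)$.

For the ODS rig, the eye at viewing azimuth $\theta$ sits at
$\pm\frac{ipd}{2}(\sin\theta, -\cos\theta, 0)$ from the rig center — the
baseline rotates with the view, so left and right never swap, in any
horizontal direction.

## Worked example

Generate a toy two-chain structure and one hundred synthetic particles, mesh
the chains, and build a scene with C2 symmetry:

```sh
cellscene fixtures --kind toy_structure  --out fx
cellscene fixtures --kind toy_particles  --out fx
cellscene mesh --structure fx/toy_structure.pdb --resolution 3.0 --out meshes --format obj
echo '{"toy": "ribo_mesh"}' > meshmap.json
cellscene particles2scene --params fx/toy_particles.json --apix 5.0 \
    --dims 256,256,128 --mesh-map meshmap.json --sym c2 --out scene.json
cellscene validate scene.json
```

prints

```
meshes/toy_structure_A.obj  (840 vertices, 1676 triangles)
meshes/toy_structure_B.obj  (1180 vertices, 2356 triangles)
scene.json: 200 instances from 100 particles
OK: 200 instances, 1 meshes, 1 annotations
```

Each chain became one closed surface mesh; the 100 particles each expanded to
2 instances under C2, and every instance in `scene.json` carries an engine
transform (location, rotator, scale) plus a key into the annotation table.
The same pattern drives `cellscene filament`, `cellscene membrane`,
`cellscene scatter`, and `cellscene panorama` / `cellscene stitch` for the
3D 360° rig (default frame: 6000×3000 pixels rendered as 60 tiles on a
10×6 grid, two eyes).

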