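"""File format readers/writers: structures, particles, paths, manifests, meshes."""

import json

import numpy as np
import pytest

from cellscene import coords, fixtures, structio
from cellscene.coords import EngineTransform, InvalidRotationError
from cellscene.meshgen import TriMesh
from cellscene.scene import AnnotationEntry, AnnotationTable, SceneInstance, SceneManifest
from cellscene.structio import (
    EmptyInputError,
    ManifestValidationError,
    ManifestVersionError,
    PathParseError,
    SchemaError,
    TooShortError,
    read_particle_params,
    read_path,
    read_scene_manifest,
    read_structure,
    write_mesh,
    write_scene_manifest,
)

WATER_ONLY_PDB = """\
HETATM    1  O   HOH A   1      10.000  10.000  10.000  1.00  0.00           O
HETATM    2  O   HOH A   2      13.000  10.000  10.000  1.00  0.00           O
END
"""


class TestReadStructure:
    def test_toy_pdb_round_trip(self, tmp_path, toy_structure_pair):
        st, pdb = toy_structure_pair
        p = tmp_path / "toy.pdb"
        p.write_text(pdb)
        rd = read_structure(p)
        assert rd.chain_ids == ["A", "B"]
        assert all(len(c.atoms) == 3 for c in rd.chains)
        assert np.array_equal(rd.coordinates(), st.coordinates())

    def test_water_only_pdb_is_empty_under_defaults(self, tmp_path):
        p = tmp_path / "water.pdb"
        p.write_text(WATER_ONLY_PDB)
        with pytest.raises(EmptyInputError):
            read_structure(p)
        # hetero included: water atoms are readable
        st = read_structure(p, include_hetero=True)
        assert sum(len(c.atoms) for c in st.chains) == 2

    def test_mmcif_matches_pdb_coordinates(self, tmp_path, toy_structure_pair):
        import gemmi

        _, pdb = toy_structure_pair
        p = tmp_path / "toy.pdb"
        p.write_text(pdb)
        st = gemmi.read_structure(str(p))
        st.setup_entities()
        cif = tmp_path / "toy.cif"
        st.make_mmcif_document().write_file(str(cif))
        a = read_structure(p).coordinates()
        b = read_structure(cif).coordinates()
        assert a.shape == b.shape
        assert np.max(np.abs(a - b)) < 1e-3

    def test_altloc_keeps_a_only(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        st = read_structure(p)
        assert sum(len(c.atoms) for c in st.chains) == 2
        assert np.allclose(st.chains[0].atoms[0].position, [0, 0, 0])


class TestParticleParams:
    def _write(self, tmp_path, records):
        p = tmp_path / "ptcls.json"
        p.write_text(json.dumps(records))
        return p

    def test_identity_matrix_record(self, tmp_path):
        p = self._write(
            tmp_path,
            [
                {
                    "particle_id": "p0",
                    "tomogram_id": "t",
                    "center_voxel": [1, 2, 3],
                    "matrix": [1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0],
                }
            ],
        )
        (rec,) = read_particle_params(p)
        assert rec.alignment.isclose(coords.Transform3D.identity())
        assert np.allclose(rec.center_voxel, [1, 2, 3])

    def test_euler_and_matrix_forms_agree(self, tmp_path):
        R = coords.euler_to_rotation(30, 40, 50)
        m = [float(x) for x in np.hstack([R, np.zeros((3, 1))]).ravel()]
        base = {"particle_id": "p", "tomogram_id": "t", "center_voxel": [0, 0, 0]}
        p = self._write(
            tmp_path,
            [
                dict(base, matrix=m),
                dict(base, euler={"az": 30, "alt": 40, "phi": 50}),
            ],
        )
        a, b = read_particle_params(p)
        assert np.max(np.abs(a.alignment.rotation - b.alignment.rotation)) < 1e-9
        assert np.max(np.abs(a.alignment.rotation - R)) < 1e-9

    @pytest.mark.parametrize("missing", ["center_voxel", "tomogram_id", "particle_id"])
    def test_missing_key_names_the_key(self, tmp_path, missing):
        rec = {
            "particle_id": "p",
            "tomogram_id": "t",
            "center_voxel": [0, 0, 0],
            "matrix": [1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0],
        }
        del rec[missing]
        with pytest.raises(SchemaError, match=missing):
            read_particle_params(self._write(tmp_path, [rec]))

    def test_missing_alignment_is_schema_error(self, tmp_path):
        rec = {"particle_id": "p", "tomogram_id": "t", "center_voxel": [0, 0, 0]}
        with pytest.raises(SchemaError, match="matrix"):
            read_particle_params(self._write(tmp_path, [rec]))

    def test_non_orthonormal_matrix_rejected(self, tmp_path):
        rec = {
            "particle_id": "p",
            "tomogram_id": "t",
            "center_voxel": [0, 0, 0],
            "matrix": [1.01, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0],
        }
        with pytest.raises(InvalidRotationError):
            read_particle_params(self._write(tmp_path, [rec]))

    def test_order_preserved_and_write_round_trip(self, tmp_path, toy_frame):
        text, _ = fixtures.make_toy_particles(20, toy_frame, seed=9)
        p = tmp_path / "in.json"
        p.write_text(text)
        recs = read_particle_params(p)
        assert [r.particle_id for r in recs] == [f"p{i:04d}" for i in range(20)]
        out = tmp_path / "out.json"
        structio.write_particle_params(recs, out)
        again = read_particle_params(out)
        for a, b in zip(recs, again):
            assert a.particle_id == b.particle_id
            assert a.alignment.isclose(b.alignment, tol=1e-9)

    def test_eman2_layout_shim(self, tmp_path):
        recs = [
            {
                "coord": [10, 20, 30],
                "xform.align3d": {"matrix": [1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0]},
                "score": -1.5,
                "class": 2,
            }
        ]
        p = self._write(tmp_path, recs)
        (rec,) = read_particle_params(p, eman2_layout=True)
        assert np.allclose(rec.center_voxel, [10, 20, 30])
        assert rec.class_label == "2"
        assert rec.score == -1.5


class TestReadPath:
    def test_text_triplets(self, tmp_path):
        p = tmp_path / "path.txt"
        p.write_text("0 0 0\n0 0 10\n0 0 20\n")
        path = read_path(p, "text")
        assert np.array_equal(path.points, [[0, 0, 0], [0, 0, 10], [0, 0, 20]])

    def test_bad_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 0 0\n1 2\n0 0 20\n")
        with pytest.raises(PathParseError, match="line 2"):
            read_path(p, "text")

    def test_too_short(self, tmp_path):
        p = tmp_path / "one.txt"
        p.write_text("0 0 0\n")
        with pytest.raises(TooShortError):
            read_path(p, "text")

    def test_calpha_ignores_non_ca_atoms(self, tmp_path):
        pdb = (
            "ATOM      1  N   ALA A   1       0.000   0.000  -1.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  CB  ALA A   1       1.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      4  CA  ALA A   2       0.000   0.000   3.800  1.00  0.00           C\n"
            "ATOM      5  CB  ALA A   2       1.000   0.000   3.800  1.00  0.00           C\n"
            "ATOM      6  CA  ALA A   3       0.000   0.000   7.600  1.00  0.00           C\n"
            "END\n"
        )
        p = tmp_path / "trace.pdb"
        p.write_text(pdb)
        path = read_path(p, "calpha")
        assert len(path.points) == 3  # one per residue
        assert np.allclose(path.points[:, 2], [0.0, 3.8, 7.6])


def _two_instance_scene():
    return SceneManifest(
        meshes={"ribo": {"label": "ribosome"}, "spike": {}},
        instances=[
            SceneInstance("i0", "ribo", EngineTransform([1.5, -2.25, 3.0], (10.0, 20.0, 30.0)), "ribo_key", 12.5),
            SceneInstance("i1", "spike", EngineTransform([0, 0, 0], (0, 0, 0), 2.0), "", 5.0),
        ],
        annotations=AnnotationTable({"ribo_key": AnnotationEntry("ribosome", "translation machine", "PDB 4V6X")}),
    )


class TestSceneManifestIO:
    def test_empty_scene_round_trip(self, tmp_path):
        p = tmp_path / "empty.json"
        write_scene_manifest(SceneManifest(), p)
        scene = read_scene_manifest(p)
        assert scene.instances == [] and scene.meshes == {}

    def test_two_instance_round_trip(self, tmp_path):
        p = tmp_path / "scene.json"
        s = _two_instance_scene()
        write_scene_manifest(s, p)
        r = read_scene_manifest(p)
        assert [i.instance_id for i in r.instances] == ["i0", "i1"]
        for a, b in zip(s.instances, r.instances):
            assert np.max(np.abs(a.transform.location - b.transform.location)) < 1e-9
            assert a.transform.rotator == b.transform.rotator
            assert a.transform.scale == b.transform.scale
            assert a.bounding_radius == b.bounding_radius
        assert r.annotations == s.annotations

    def test_absent_mesh_reference_fails_validation(self, tmp_path):
        p = tmp_path / "bad.json"
        doc = {
            "schema_version": "1.0",
            "meshes": {},
            "instances": [
                {"instance_id": "i0", "mesh_id": "ghost", "location": [0, 0, 0],
                 "rotator": [0, 0, 0], "scale": 1.0, "annotation_key": "", "bounding_radius": 1.0}
            ],
            "annotations": {},
        }
        p.write_text(json.dumps(doc))
        with pytest.raises(ManifestValidationError, match="ghost"):
            read_scene_manifest(p)

    def test_unknown_schema_version(self, tmp_path):
        p = tmp_path / "v9.json"
        p.write_text(json.dumps({"schema_version": "9.9"}))
        with pytest.raises(ManifestVersionError):
            read_scene_manifest(p)

    def test_write_refuses_invalid_scene(self, tmp_path):
        s = _two_instance_scene()
        s.instances.append(s.instances[0])  # duplicate id
        with pytest.raises(ValueError, match="duplicate"):
            write_scene_manifest(s, tmp_path / "dup.json")


class TestWriteMesh:
    def test_obj_line_counts_for_unit_triangle(self, tmp_path):
        mesh = TriMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        p = tmp_path / "tri.obj"
        write_mesh(mesh, p)
        lines = p.read_text().splitlines()
        assert sum(l.startswith("v ") for l in lines) == 3
        assert sum(l.startswith("f ") for l in lines) == 1
        assert "f 1 2 3" in lines  # 1-based indices

    def test_obj_round_trip_against_trimesh_parser(self, tmp_path, rng):
        import trimesh

        verts = rng.uniform(-50, 50, size=(60, 3))
        faces = rng.integers(0, 60, size=(100, 3))
        faces = faces[(faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])]
        mesh = TriMesh(verts, faces)
        p = tmp_path / "rand.obj"
        write_mesh(mesh, p)
        tm = trimesh.load(str(p), file_type="obj", process=False, maintain_order=True)
        assert np.max(np.abs(np.asarray(tm.vertices) - mesh.vertices)) < 1e-6
        assert np.array_equal(np.asarray(tm.faces), mesh.triangles)

    def test_glb_is_a_valid_binary_gltf(self, tmp_path):
        import trimesh

        mesh = TriMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], [[0, 1, 2], [0, 1, 3]])
        p = tmp_path / "mesh.glb"
        write_mesh(mesh, p)
        assert p.read_bytes()[:4] == b"glTF"
        loaded = trimesh.load(str(p), file_type="glb", process=False)
        geom = list(loaded.geometry.values())[0]
        assert len(geom.faces) == 2

    def test_empty_mesh_rejected(self, tmp_path):
        with pytest.raises(EmptyInputError):
            write_mesh(TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int)), tmp_path / "e.obj")
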