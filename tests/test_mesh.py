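import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from toothseg.mesh import (
    CODE_TO_INDEX,
    GINGIVA,
    TOOTH_CODES,
    FaceLabeling,
    MeshValidationError,
    ToothClass,
    TriangleMesh,
    face_adjacency,
    face_areas,
    label_boundary_vertices,
    read_labels,
    read_mesh,
    write_labels,
    write_mesh,
)


class TestToothClass:
    def test_code_index_bijection(self):
        assert len(TOOTH_CODES) == 17
        for i, code in enumerate(TOOTH_CODES):
            assert ToothClass.from_code(code).index == i
            assert ToothClass(i).code == code
        assert GINGIVA.index == 16 and GINGIVA.is_gingiva

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            ToothClass.from_code("X3")


class TestMeshIO:
    def test_binary_stl_round_trip(self, two_triangle_mesh, tmp_path):
        path = tmp_path / "m.stl"
        write_mesh(two_triangle_mesh, path)
        back = read_mesh(path)
        assert back.n_faces == 2
        # STL stores per-face vertices; compare triangle soup geometry
        np.testing.assert_allclose(
            np.sort(back.triangles().reshape(-1, 3), axis=0),
            np.sort(two_triangle_mesh.triangles().reshape(-1, 3), axis=0),
            atol=1e-6,
        )

    @pytest.mark.parametrize("suffix", [".ply", ".obj"])
    def test_indexed_round_trip_preserves_arrays(self, suffix, tmp_path, default_case):
        path = tmp_path / f"m{suffix}"
        write_mesh(default_case.mesh, path)
        back = read_mesh(path)
        np.testing.assert_allclose(back.vertices, default_case.mesh.vertices, atol=1e-4)
        np.testing.assert_array_equal(back.faces, default_case.mesh.faces)

    def test_degenerate_faces_dropped_with_warning(self, tmp_path, caplog):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [2, 0, 0]], dtype=float)
        faces = np.vstack([[0, 1, 2]] * 10 + [[0, 1, 3]])  # last is zero-area (collinear)
        import trimesh

        trimesh.Trimesh(verts, faces, process=False).export(str(tmp_path / "d.ply"))
        with caplog.at_level("WARNING"):
            mesh = read_mesh(tmp_path / "d.ply")
        assert mesh.n_faces == 10
        assert any("degenerate" in r.message for r in caplog.records)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(IOError):
            read_mesh(tmp_path / "absent.stl")

    def test_zero_faces_rejected(self):
        with pytest.raises(MeshValidationError):
            TriangleMesh(np.zeros((3, 3)), np.empty((0, 3), dtype=int))


class TestLabelIO:
    def test_write_format(self, tmp_path):
        labeling = FaceLabeling.from_codes(["G", "G", "L1"])
        path = tmp_path / "m.labels.txt"
        write_labels(labeling, path)
        assert path.read_text() == "G\nG\nL1\n"

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(TOOTH_CODES), min_size=1, max_size=40))
    def test_round_trip_lossless(self, codes):
        import tempfile, os

        labeling = FaceLabeling.from_codes(codes)
        fd, path = tempfile.mkstemp()
        os.close(fd)
        try:
            write_labels(labeling, path)
            back = read_labels(path)
            np.testing.assert_array_equal(back.indices, labeling.indices)
        finally:
            os.unlink(path)

    def test_length_mismatch_rejected(self, two_triangle_mesh, tmp_path):
        path = tmp_path / "short.labels.txt"
        path.write_text("G\nG\n")
        three_face = TriangleMesh(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 0, 0.0]]),
            np.array([[0, 1, 2], [1, 3, 2], [1, 4, 3]]),
        )
        with pytest.raises(MeshValidationError):
            read_labels(path, three_face)

    def test_unknown_code_rejected(self, tmp_path):
        path = tmp_path / "bad.labels.txt"
        path.write_text("G\nZZ\n")
        with pytest.raises(ValueError):
            read_labels(path)

    def test_json_header_variant_accepted(self, tmp_path):
        path = tmp_path / "hdr.labels.txt"
        path.write_text('{"checksum": "abc"}\nG\nL1\n')
        back = read_labels(path)
        assert back.codes() == ["G", "L1"]


def heron_area(a, b, c):
    la, lb, lc = (
        np.linalg.norm(b - c),
        np.linalg.norm(a - c),
        np.linalg.norm(a - b),
    )
    s = (la + lb + lc) / 2
    return np.sqrt(max(s * (s - la) * (s - lb) * (s - lc), 0.0))


class TestFaceAreas:
    def test_unit_right_triangle(self):
        mesh = TriangleMesh(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float), [[0, 1, 2]]
        )
        assert face_areas(mesh)[0] == pytest.approx(0.5)

    def test_scaling_quadruples_area(self, default_case):
        mesh = default_case.mesh
        scaled = TriangleMesh(2 * mesh.vertices, mesh.faces)
        np.testing.assert_allclose(face_areas(scaled), 4 * face_areas(mesh), rtol=1e-12)

    def test_unit_cube_total_area(self, unit_cube_mesh):
        assert face_areas(unit_cube_mesh).sum() == pytest.approx(6.0)

    def test_matches_heron_oracle(self):
        rng = np.random.default_rng(0)
        verts = rng.uniform(-10, 10, (60, 3))
        faces = np.arange(60).reshape(20, 3)
        mesh = TriangleMesh(verts, faces)
        expected = [heron_area(*verts[f]) for f in faces]
        np.testing.assert_allclose(face_areas(mesh), expected, rtol=1e-9)


class TestLabelBoundary:
    def test_uniform_labeling_has_no_boundary(self, two_triangle_mesh):
        labeling = FaceLabeling.from_codes(["G", "G"])
        assert len(label_boundary_vertices(two_triangle_mesh, labeling, GINGIVA)) == 0

    def test_two_triangle_transition(self, two_triangle_mesh):
        labeling = FaceLabeling.from_codes(["L1", "G"])
        pts = label_boundary_vertices(
            two_triangle_mesh, labeling, ToothClass.from_code("L1")
        )
        # the shared edge is (1,2)
        expected = two_triangle_mesh.vertices[[1, 2]]
        np.testing.assert_allclose(np.sort(pts, axis=0), np.sort(expected, axis=0))

    def test_boundary_symmetric_under_complement(self, default_case):
        mesh, labeling = default_case.mesh, default_case.labeling
        cls = labeling.present_teeth()[0]
        other = ToothClass(1 if cls.index == 0 else 0)
        b1 = label_boundary_vertices(mesh, labeling, cls)
        # collapse everything that is not cls into one complementary class:
        # the transition set, hence the boundary, must be identical
        complement = FaceLabeling(
            np.where(labeling.indices == cls.index, cls.index, other.index).astype(
                np.int16
            )
        )
        b2 = label_boundary_vertices(mesh, complement, other)
        assert {tuple(p) for p in b1} == {tuple(p) for p in b2}

    def test_patch_boundary_forms_closed_loop(self, default_case):
        """Boundary vertices of a tooth form a single closed vertex cycle."""
        mesh, labeling = default_case.mesh, default_case.labeling
        cls = labeling.present_teeth()[2]
        pts = label_boundary_vertices(mesh, labeling, cls)
        assert len(pts) >= 3
        # every boundary vertex should have exactly two boundary-vertex
        # neighbors along label-transition edges
        in_cls = labeling.indices == cls.index
        from collections import defaultdict

        edge_faces = defaultdict(list)
        for fi, f in enumerate(mesh.faces):
            for u, v in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                edge_faces[tuple(sorted((int(u), int(v))))].append(fi)
        degree = defaultdict(int)
        for (u, v), fs in edge_faces.items():
            if len(fs) == 2 and in_cls[fs[0]] != in_cls[fs[1]]:
                degree[u] += 1
                degree[v] += 1
        assert degree and all(d == 2 for d in degree.values())


class TestAdjacency:
    def test_symmetric_and_bounded(self, default_case):
        adj = face_adjacency(default_case.mesh)
        for fi, nbrs in enumerate(adj):
            assert len(nbrs) <= 3
            for nb in nbrs:
                assert fi in adj[nb]
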