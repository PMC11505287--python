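import numpy as np
import pytest

from toothseg.mesh import GINGIVA_INDEX, FaceLabeling, TriangleMesh, ToothClass
from toothseg.synthetic import JawSpec, generate_jaw
from toothseg.views import CameraPose, render_sequence, render_view, sample_views
from toothseg.voting import (
    CertaintyTable,
    build_certainty,
    cca_cleanup,
    region_voting,
    unproject_masks,
    visibility_counts,
)


def table_from_dense(cert_like: np.ndarray, denom: int = 4) -> CertaintyTable:
    """Build a table whose certainty matrix equals cert_like (values k/denom)."""
    hits = np.round(np.asarray(cert_like) * denom).astype(np.int64)
    vis = np.full(hits.shape, denom, dtype=np.int64)
    return CertaintyTable(hits, vis)


class TestUnprojectMasks:
    def test_all_zero_masks_empty(self, default_case):
        poses = sample_views(default_case.landmarks.tooth_pair(4), n=3)
        seq = render_sequence(default_case.mesh, poses, 64)
        masks = np.zeros((3, 64, 64), dtype=np.uint8)
        face_set, hits = unproject_masks(masks, seq.records, default_case.mesh.n_faces)
        assert len(face_set) == 0 and not hits.any()

    def test_single_pixel_single_triangle(self):
        mesh = TriangleMesh(
            np.array([[-20, -20, 0], [20, -20, 0], [0, 20, 0.0]]), [[0, 1, 2]]
        )
        pose = CameraPose([0, 0, 10.0], [0, 0, 0.0], [0, 1, 0.0])
        maps, rec = render_view(mesh, pose, 16)
        masks = np.zeros((1, 16, 16), dtype=np.uint8)
        masks[0, 8, 8] = 1
        face_set, hits = unproject_masks(masks, [rec], 1)
        assert list(face_set) == [0] and hits[0] == 1

    def test_per_view_hit_counting(self):
        """A face hit by many pixels in one view counts once per view."""
        mesh = TriangleMesh(
            np.array([[-20, -20, 0], [20, -20, 0], [0, 20, 0.0]]), [[0, 1, 2]]
        )
        pose = CameraPose([0, 0, 10.0], [0, 0, 0.0], [0, 1, 0.0])
        _, rec = render_view(mesh, pose, 16)
        masks = np.ones((2, 16, 16), dtype=np.uint8)
        _, hits = unproject_masks(masks, [rec, rec], 1)
        assert hits[0] == 2  # two views, not hundreds of pixels

    def test_occluded_face_never_enters(self):
        v = np.array(
            [[-5, -5, 5], [5, -5, 5], [5, 5, 5], [-5, 5, 5],
             [-4, -4, 0], [4, -4, 0], [4, 4, 0], [-4, 4, 0.0]]
        )
        f = [[0, 1, 2], [0, 2, 3], [4, 5, 6], [4, 6, 7]]
        mesh = TriangleMesh(v, f)
        pose = CameraPose([0, 0, 20.0], [0, 0, 0.0], [0, 1, 0.0])
        _, rec = render_view(mesh, pose, 64)
        face_set, _ = unproject_masks(np.ones((1, 64, 64)), [rec], 4)
        assert set(face_set) <= {0, 1}

    def test_exhaustive_oracle_equivalence(self, default_case):
        """unproject + visibility match a per-pixel brute-force recount."""
        poses = sample_views(default_case.landmarks.tooth_pair(9), n=5)
        seq = render_sequence(default_case.mesh, poses, 48)
        rng = np.random.default_rng(0)
        masks = (rng.random((5, 48, 48)) > 0.5).astype(np.uint8)
        face_set, hits = unproject_masks(masks, seq.records, default_case.mesh.n_faces)
        vis = visibility_counts(seq.records, default_case.mesh.n_faces)
        # brute force: loop every pixel of every view
        hits_bf = np.zeros(default_case.mesh.n_faces, dtype=int)
        vis_bf = np.zeros(default_case.mesh.n_faces, dtype=int)
        for v in range(5):
            seen_hit, seen_vis = set(), set()
            fh = seq.records[v].first_hit
            for i in range(48):
                for j in range(48):
                    fidx = fh[i, j]
                    if fidx < 0:
                        continue
                    seen_vis.add(int(fidx))
                    if masks[v, i, j]:
                        seen_hit.add(int(fidx))
            for fidx in seen_hit:
                hits_bf[fidx] += 1
            for fidx in seen_vis:
                vis_bf[fidx] += 1
        np.testing.assert_array_equal(hits, hits_bf)
        np.testing.assert_array_equal(vis, vis_bf)
        np.testing.assert_array_equal(face_set, np.flatnonzero(hits_bf))


class TestCertainty:
    def test_ratios(self):
        hits = {3: np.array([3, 4, 0])}
        vis = {3: np.array([4, 4, 0])}
        table = build_certainty(hits, vis, 3)
        np.testing.assert_allclose(table.certainty[3], [0.75, 1.0, 0.0])

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            CertaintyTable(np.array([[2]]), np.array([[1]]))


class TestRegionVoting:
    def test_argmax_and_gingiva_fallback(self):
        cert = np.zeros((16, 3))
        cert[0, 0] = 0.8  # L8 wins face 0
        cert[1, 0] = 0.5
        # face 1: all zeros -> gingiva; face 2: tie L8/L7 -> lower index L8
        cert[0, 2] = 0.6
        cert[1, 2] = 0.6
        labeling = region_voting(table_from_dense(cert, denom=10))
        assert labeling.indices[0] == 0
        assert labeling.indices[1] == GINGIVA_INDEX
        assert labeling.indices[2] == 0

    def test_single_assignment(self):
        rng = np.random.default_rng(1)
        cert = rng.random((16, 40)) * (rng.random((16, 40)) > 0.5)
        labeling = region_voting(table_from_dense(np.round(cert * 8) / 8, denom=8))
        assert labeling.indices.shape == (40,)  # one label per face, by construction


def strip_mesh(n):
    """Strip of n triangles in a row (fan on shared vertices)."""
    verts = []
    faces = []
    for i in range(n + 1):
        verts.append([i, 0, 0])
        verts.append([i, 1, 0])
    for i in range(n):
        a, b, c, d = 2 * i, 2 * i + 1, 2 * i + 2, 2 * i + 3
        faces.append([a, b, c])
        faces.append([b, d, c])
    return TriangleMesh(np.array(verts, dtype=float), np.array(faces[: n]))


class TestCCACleanup:
    def make_table(self, labels, n_classes=16, denom=4, extra=None):
        n = len(labels)
        hits = np.zeros((n_classes, n), dtype=np.int64)
        vis = np.full((n_classes, n), denom, dtype=np.int64)
        for f, c in enumerate(labels):
            if c < n_classes:
                hits[c, f] = denom
        if extra:
            for (c, f), v in extra.items():
                hits[c, f] = v
        return CertaintyTable(hits, vis)

    def test_single_component_fixed_point(self, default_case):
        table = self.make_table(default_case.labeling.indices)
        out = cca_cleanup(default_case.mesh, default_case.labeling, table)
        np.testing.assert_array_equal(out.indices, default_case.labeling.indices)

    def test_largest_component_kept(self):
        mesh = strip_mesh(13)
        labels = np.full(13, GINGIVA_INDEX, dtype=np.int16)
        labels[0:10] = 2  # 10-face component
        labels[11:13] = 2  # separated 2-face satellite (face 10 is gingiva)
        labeling = FaceLabeling(labels)
        table = self.make_table(labels)
        out = cca_cleanup(mesh, labeling, table)
        assert (out.indices[0:10] == 2).all()
        assert (out.indices[11:13] == GINGIVA_INDEX).all()

    def test_discarded_faces_fall_back_to_next_certainty(self):
        mesh = strip_mesh(13)
        labels = np.full(13, GINGIVA_INDEX, dtype=np.int16)
        labels[0:6] = 2
        labels[7:13] = 5  # class 5 region adjacent to face 11
        labels[11] = 2  # satellite of class 2 embedded in class-5 region
        labeling = FaceLabeling(labels)
        # face 11 has nonzero certainty for class 5 as well
        table = self.make_table(labels, extra={(5, 11): 2})
        out = cca_cleanup(mesh, labeling, table)
        assert out.indices[11] == 5
        # face 12 (cut off from class 5 by the satellite) rejoins class 5
        # once face 11 is reassigned
        assert out.indices[12] == 5

    def test_zero_certainty_fallback_to_gingiva(self):
        mesh = strip_mesh(13)
        labels = np.full(13, GINGIVA_INDEX, dtype=np.int16)
        labels[0:6] = 2
        labels[11] = 2
        labeling = FaceLabeling(labels)
        table = self.make_table(labels)
        out = cca_cleanup(mesh, labeling, table)
        assert out.indices[11] == GINGIVA_INDEX

    def test_output_single_component_per_class(self, default_case):
        """Corrupting a labeling with satellites, cleanup restores exactly one
        component per present class."""
        from toothseg.synthetic import count_label_components

        rng = np.random.default_rng(2)
        labels = default_case.labeling.indices.copy()
        ging = np.flatnonzero(labels == GINGIVA_INDEX)
        for cls in (0, 5, 9):
            labels[rng.choice(ging, size=3, replace=False)] = cls
        corrupted = FaceLabeling(labels)
        table = self.make_table(labels)
        out = cca_cleanup(default_case.mesh, corrupted, table)
        for t in out.present_teeth():
            assert count_label_components(default_case.mesh, out, t.index) == 1
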