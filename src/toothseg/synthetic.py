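"""Synthetic dental-arch generator and tessellation perturbations.

``generate_jaw`` builds a labeled single-arch mesh from a ``JawSpec``
parameter set: convex ovoid tooth crowns (superellipse-footprint domes)
placed along a parabolic arch on a gently corrugated gingiva sheet,
composited as a height field (which guarantees each tooth region is a single
connected component), triangulated on a regular grid at roughly the target
edge length.  Orthodontic anomalies are knobs: missing teeth, positional
jitter (crowding), rotations and eruption offsets (retention).

The three tessellation perturbations emulate scanner/remesher variability:
random vertex displacement (RVD), planar edge-flip optimization (PFO) and
explicit isotropic remeshing (ER).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import arch
from ._geom import SurfaceIndex
from .align import LandmarkSet, RigidTransform
from .mesh import (
    GINGIVA_INDEX,
    FaceLabeling,
    ToothClass,
    TriangleMesh,
    face_adjacency_pairs,
)


class GenerationError(RuntimeError):
    pass


class RemeshingError(RuntimeError):
    pass


@dataclass
class JawSpec:
    """Parameters of one synthetic dental arch.  All lengths in mm."""

    arch_width: float = 64.0
    arch_depth: float = 54.0
    present: np.ndarray = field(default_factory=lambda: np.ones(16, dtype=bool))
    crown_scale: np.ndarray = field(default_factory=lambda: np.ones(16))
    rotation: np.ndarray = field(default_factory=lambda: np.zeros(16))  # rad
    jitter: np.ndarray = field(default_factory=lambda: np.zeros(16))  # mm
    eruption_offset: np.ndarray = field(default_factory=lambda: np.zeros(16))  # mm
    corrugation_amp: float = 0.25
    target_edge: float = 0.5
    band_width: float = 6.5  # gingiva sheet half-width around the arch curve
    seed: int = 0

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool).reshape(16)
        self.crown_scale = np.asarray(self.crown_scale, dtype=np.float64).reshape(16)
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(16)
        self.jitter = np.asarray(self.jitter, dtype=np.float64).reshape(16)
        self.eruption_offset = np.asarray(self.eruption_offset, dtype=np.float64).reshape(16)
        if self.arch_width <= 0 or self.arch_depth <= 0 or self.target_edge <= 0:
            raise ValueError("sizes must be positive")
        if np.any(self.crown_scale <= 0):
            raise ValueError("crown scales must be positive")
        if not self.present.any():
            raise ValueError("at least one tooth must be present")


@dataclass
class SyntheticCase:
    mesh: TriangleMesh
    labeling: FaceLabeling
    landmarks: LandmarkSet

    def validate(self) -> None:
        if len(self.labeling) != self.mesh.n_faces:
            raise GenerationError("labeling length mismatch")
        present_lbl = {t.index for t in self.labeling.present_teeth()}
        present_lm = set(np.flatnonzero(self.landmarks.present))
        if present_lbl != present_lm:
            raise GenerationError(
                f"label/landmark presence mismatch: {present_lbl ^ present_lm}"
            )
        for idx, count in _count_components(self.mesh, self.labeling).items():
            if count != 1:
                raise GenerationError(
                    f"tooth {ToothClass(idx).code} forms {count} components"
                )


def _components_of_faces(
    members: np.ndarray, pairs: np.ndarray, n_faces: int
) -> np.ndarray:
    remap = -np.ones(n_faces, dtype=np.int64)
    remap[members] = np.arange(len(members))
    if len(pairs):
        sel = (remap[pairs[:, 0]] >= 0) & (remap[pairs[:, 1]] >= 0)
        sub = remap[pairs[sel]]
    else:
        sub = np.empty((0, 2), dtype=np.int64)
    m = coo_matrix(
        (np.ones(len(sub)), (sub[:, 0], sub[:, 1])), shape=(len(members),) * 2
    )
    _, comp = connected_components(m, directed=False)
    return comp


def _count_components(mesh: TriangleMesh, labeling: FaceLabeling) -> dict[int, int]:
    pairs = face_adjacency_pairs(mesh)
    out: dict[int, int] = {}
    for idx in np.unique(labeling.indices):
        if idx == GINGIVA_INDEX:
            continue
        out[int(idx)] = count_label_components(mesh, labeling, int(idx), pairs)
    return out


def count_label_components(
    mesh: TriangleMesh,
    labeling: FaceLabeling,
    class_index: int,
    pairs: np.ndarray | None = None,
) -> int:
    """Number of edge-connected components among faces of one class."""
    if pairs is None:
        pairs = face_adjacency_pairs(mesh)
    members = np.flatnonzero(labeling.indices == class_index)
    if len(members) == 0:
        return 0
    remap = -np.ones(mesh.n_faces, dtype=np.int64)
    remap[members] = np.arange(len(members))
    if len(pairs):
        sel = (remap[pairs[:, 0]] >= 0) & (remap[pairs[:, 1]] >= 0)
        sub = remap[pairs[sel]]
    else:
        sub = np.empty((0, 2), dtype=np.int64)
    m = coo_matrix(
        (np.ones(len(sub)), (sub[:, 0], sub[:, 1])), shape=(len(members),) * 2
    )
    n, _ = connected_components(m, directed=False)
    return int(n)


# ---------------------------------------------------------------------------
# Generation


def _crown_heights(spec: JawSpec, xy: np.ndarray, params: list[dict]) -> np.ndarray:
    """(n_points, 16) crown height contributions at xy positions."""
    h = np.zeros((len(xy), 16))
    for p in params:
        if p is None:
            continue
        rel = xy - p["center"][None, :]
        xi = rel @ p["md_dir"]
        eta = rel @ p["bl_dir"]
        rho_p = (np.abs(xi) / p["a"]) ** 3 + (np.abs(eta) / p["b"]) ** 3
        rho = rho_p ** (1.0 / 3.0)
        inside = rho < 1.0
        # paraboloid dome: gentle apex curvature (radius ~ a^2/2h, a few mm,
        # as on real crowns) so the occlusal surface is resolvable at the
        # default tessellation density
        h[inside, p["slot"]] = p["h"] * (1.0 - rho[inside] ** 2)
    return h


def _tooth_params(spec: JawSpec, rng: np.random.Generator) -> list[dict | None]:
    t_slots = arch.tooth_slot_parameters(spec.arch_width, spec.arch_depth)
    centers = arch.arch_point(t_slots, spec.arch_width, spec.arch_depth)[:, :2]
    tangents = arch.arch_tangent(t_slots, spec.arch_width, spec.arch_depth)[:, :2]
    types = np.array(list(range(8, 0, -1)) + list(range(1, 9)))
    params: list[dict | None] = []
    for slot in range(16):
        # draw jitter for every slot so presence flags do not shift the stream
        ang = rng.uniform(0, 2 * np.pi)
        rad = spec.jitter[slot] * np.sqrt(rng.uniform())
        if not spec.present[slot]:
            params.append(None)
            continue
        ty = types[slot]
        width = arch.CROWN_WIDTHS_MM[ty - 1] * spec.crown_scale[slot]
        height = arch.CROWN_HEIGHTS_MM[ty - 1] * spec.crown_scale[slot]
        height = height - spec.eruption_offset[slot]
        if height <= 0.5:
            raise GenerationError(f"eruption offset flattens tooth slot {slot}")
        center = centers[slot] + rad * np.array([np.cos(ang), np.sin(ang)])
        tang = tangents[slot]
        rot = spec.rotation[slot]
        c, s = np.cos(rot), np.sin(rot)
        md = np.array([c * tang[0] - s * tang[1], s * tang[0] + c * tang[1]])
        bl = np.array([-md[1], md[0]])
        params.append(
            {
                "slot": slot,
                "center": center,
                "md_dir": md,
                "bl_dir": bl,
                "a": 0.5 * width - 0.25,
                "b": 0.48 * width,
                "h": height,
            }
        )
    return params


def _base_z(spec: JawSpec, xy: np.ndarray) -> np.ndarray:
    return spec.corrugation_amp * np.sin(0.7 * xy[:, 0]) * np.sin(0.9 * xy[:, 1] + 1.3)


def generate_jaw(spec: JawSpec) -> SyntheticCase:
    """Generate one synthetic labeled arch in canonical pose.

    Deterministic for a fixed spec (including its seed).  Raises
    ``GenerationError`` when crowding merges or splits a tooth region.
    """
    rng = np.random.default_rng(spec.seed)
    params = _tooth_params(spec, rng)

    # grid over the arch band
    g = 0.85 * spec.target_edge
    t_dense = np.linspace(-1, 1, 512)
    arch_pts = arch.arch_point(t_dense, spec.arch_width, spec.arch_depth)[:, :2]
    lo = arch_pts.min(axis=0) - spec.band_width - 1.0
    hi = arch_pts.max(axis=0) + spec.band_width + 1.0
    nx = int(np.ceil((hi[0] - lo[0]) / g)) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / g)) + 1
    xs = lo[0] + g * np.arange(nx)
    ys = lo[1] + g * np.arange(ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    xy = np.stack([gx.ravel(), gy.ravel()], axis=1)

    from scipy.spatial import cKDTree

    d_arch, _ = cKDTree(arch_pts).query(xy)
    mask = d_arch <= spec.band_width
    for p in params:
        if p is not None:
            rel = xy - p["center"][None, :]
            mask |= np.hypot(rel @ p["md_dir"], rel @ p["bl_dir"]) <= max(p["a"], p["b"]) + 1.0
    mask2d = mask.reshape(nx, ny)

    vidx = -np.ones((nx, ny), dtype=np.int64)
    sel = np.flatnonzero(mask)
    vidx.ravel()[sel] = np.arange(len(sel))
    pts_xy = xy[sel]
    z = _base_z(spec, pts_xy) + _crown_heights(spec, pts_xy, params).max(axis=1)
    vertices = np.column_stack([pts_xy, z])

    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            v00, v10 = vidx[i, j], vidx[i + 1, j]
            v01, v11 = vidx[i, j + 1], vidx[i + 1, j + 1]
            have = [v >= 0 for v in (v00, v10, v11, v01)]
            if all(have):
                faces.append((v00, v10, v11))
                faces.append((v00, v11, v01))
            elif have[0] and have[1] and have[2]:
                faces.append((v00, v10, v11))
            elif have[0] and have[2] and have[3]:
                faces.append((v00, v11, v01))
            elif have[0] and have[1] and have[3]:
                faces.append((v00, v10, v01))
            elif have[1] and have[2] and have[3]:
                faces.append((v10, v11, v01))
    mesh = TriangleMesh(vertices, np.array(faces, dtype=np.int64))

    # face labels from crown contribution at centroids
    centroids = mesh.triangles().mean(axis=1)[:, :2]
    h = _crown_heights(spec, centroids, params)
    winner = np.argmax(h, axis=1)
    hmax = h[np.arange(len(h)), winner]
    labels = np.where(hmax > 0.25, winner, GINGIVA_INDEX).astype(np.int16)
    labeling = FaceLabeling(labels)

    # consistency: each present tooth must form one component.  Sub-threshold
    # slivers at the crown rim (centroid sampling noise where two crowns
    # meet) are absorbed into gingiva; any sizable secondary component means
    # the crowns genuinely collided and generation fails.
    pairs = face_adjacency_pairs(mesh)
    colliding = []
    for p in params:
        if p is None:
            continue
        slot = p["slot"]
        members = np.flatnonzero(labels == slot)
        if len(members) == 0:
            colliding.append(ToothClass(slot).code)
            continue
        comp = _components_of_faces(members, pairs, mesh.n_faces)
        n_comp = comp.max() + 1
        if n_comp == 1:
            continue
        sizes = np.bincount(comp, minlength=n_comp)
        main = int(np.argmax(sizes))
        stray = members[comp != main]
        if len(stray) <= max(3, int(0.05 * len(members))):
            labels[stray] = GINGIVA_INDEX
        else:
            colliding.append(ToothClass(slot).code)
    labeling = FaceLabeling(labels)
    if colliding:
        raise GenerationError(
            f"crowding merged or split tooth regions: {', '.join(colliding)}"
        )

    landmarks = _place_landmarks(spec, params, mesh)

    # canonical pose: xy-center on the ideal slot layout (matches the
    # canonical landmark template, whose mesial/distal offsets cancel in
    # the mean), upright along z
    t_slots = arch.tooth_slot_parameters(spec.arch_width, spec.arch_depth)
    shift = arch.arch_point(t_slots, spec.arch_width, spec.arch_depth).mean(axis=0)
    shift[2] = 0.0
    mesh = TriangleMesh(mesh.vertices - shift, mesh.faces)
    landmarks = LandmarkSet(landmarks.mesial - shift, landmarks.distal - shift)

    case = SyntheticCase(mesh, labeling, landmarks)
    case.validate()
    return case


def _place_landmarks(
    spec: JawSpec, params: list[dict | None], mesh: TriangleMesh
) -> LandmarkSet:
    t_slots = arch.tooth_slot_parameters(spec.arch_width, spec.arch_depth)
    tangents = arch.arch_tangent(t_slots, spec.arch_width, spec.arch_depth)[:, :2]
    mesial = np.full((16, 3), np.inf)
    distal = np.full((16, 3), np.inf)
    idx = SurfaceIndex(mesh)
    for slot, p in enumerate(params):
        if p is None:
            continue
        toward_mid = 1.0 if slot < 8 else -1.0
        off = tangents[slot] * (0.7 * p["a"])
        for sign, store in ((toward_mid, mesial), (-toward_mid, distal)):
            xy = p["center"] + sign * off
            zs = float(_base_z(spec, xy[None, :])[0]) + float(
                _crown_heights(spec, xy[None, :], [p]).max()
            )
            guess = np.array([xy[0], xy[1], zs])
            snapped, _, _ = idx.closest(guess[None, :])
            store[slot] = snapped[0]
    return LandmarkSet(mesial, distal)


def sample_spec(seed: int, anomaly_level: float = 1.0) -> JawSpec:
    """Draw a randomized study-condition spec: occasional missing teeth,
    mild crowding jitter, rotations, size variation and retention.

    ``anomaly_level`` scales the anomaly magnitudes (0 = ideal arch).
    """
    rng = np.random.default_rng(seed)
    present = np.ones(16, dtype=bool)
    n_missing = int(rng.integers(0, 4)) if anomaly_level > 0 else 0
    if n_missing:
        present[rng.choice(16, size=n_missing, replace=False)] = False
    lvl = anomaly_level
    erupt = np.where(rng.random(16) < 0.1 * lvl, rng.uniform(0.5, 1.5, 16), 0.0)
    return JawSpec(
        arch_width=float(rng.uniform(60, 68)),
        arch_depth=float(rng.uniform(50, 58)),
        present=present,
        crown_scale=rng.uniform(1 - 0.08 * lvl, 1 + 0.08 * lvl, 16),
        rotation=rng.uniform(-0.25 * lvl, 0.25 * lvl, 16),
        jitter=rng.uniform(0.0, 0.5 * lvl, 16),
        eruption_offset=erupt * lvl,
        corrugation_amp=float(rng.uniform(0.15, 0.35)),
        target_edge=float(rng.uniform(0.45, 0.6)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def transfer_labels(
    src_mesh: TriangleMesh, src_labeling: FaceLabeling, dst_mesh: TriangleMesh
) -> FaceLabeling:
    """Transport labels to another tessellation via nearest source face."""
    idx = SurfaceIndex(src_mesh)
    centroids = dst_mesh.triangles().mean(axis=1)
    _, _, faces = idx.closest(centroids)
    return FaceLabeling(src_labeling.indices[faces])


# ---------------------------------------------------------------------------
# Tessellation perturbations


def perturb_rvd(
    mesh: TriangleMesh, max_disp: float = 0.2, seed: int = 0
) -> TriangleMesh:
    """Random vertex displacement: each vertex moves along a uniformly random
    direction by a magnitude uniform in [0, max_disp] mm.  Topology unchanged.
    """
    if max_disp < 0:
        raise ValueError("max_disp must be >= 0")
    if max_disp == 0:
        return mesh.copy()
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=(mesh.n_vertices, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    mag = rng.uniform(0.0, max_disp, size=mesh.n_vertices)
    return TriangleMesh(mesh.vertices + direction * mag[:, None], mesh.faces.copy())


def _edge_face_map(faces: np.ndarray) -> dict[tuple[int, int], list[int]]:
    out: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            out.setdefault(key, []).append(fi)
    return out


def _min_angle(tri: np.ndarray) -> float:
    """Smallest interior angle of a triangle given (3,3) vertex positions."""
    e = np.array(
        [tri[1] - tri[0], tri[2] - tri[1], tri[0] - tri[2]], dtype=np.float64
    )
    lens = np.linalg.norm(e, axis=1)
    if np.any(lens == 0):
        return 0.0
    angles = []
    for i in range(3):
        u = -e[i - 1] / lens[i - 1]
        v = e[i] / lens[i]
        angles.append(np.arccos(np.clip(np.dot(u, v), -1, 1)))
    return float(min(angles))


def perturb_pfo(
    mesh: TriangleMesh, max_dihedral: float = np.deg2rad(15.0), max_passes: int = 10
) -> TriangleMesh:
    """Planar flipping optimization: flip interior manifold edges when the
    flip increases the minimum triangle angle across the two incident faces.

    Vertex positions are untouched.  Flips are restricted to nearly coplanar
    face pairs (dihedral below ``max_dihedral``) so the geometry the mesh
    discretizes is preserved.
    """
    verts = mesh.vertices
    faces = mesh.faces.copy()
    for _ in range(max_passes):
        efm = _edge_face_map(faces)
        edge_set = set(efm.keys())
        dirty = np.zeros(len(faces), dtype=bool)
        flipped_any = False
        for (u, v), fs in efm.items():
            if len(fs) != 2:
                continue
            f1, f2 = fs
            if dirty[f1] or dirty[f2]:
                continue
            a = [w for w in faces[f1] if w not in (u, v)][0]
            b = [w for w in faces[f2] if w not in (u, v)][0]
            if a == b:
                continue
            key_new = (a, b) if a < b else (b, a)
            if key_new in edge_set:
                continue
            n1 = np.cross(verts[faces[f1][1]] - verts[faces[f1][0]],
                          verts[faces[f1][2]] - verts[faces[f1][0]])
            n2 = np.cross(verts[faces[f2][1]] - verts[faces[f2][0]],
                          verts[faces[f2][2]] - verts[faces[f2][0]])
            l1, l2 = np.linalg.norm(n1), np.linalg.norm(n2)
            if l1 == 0 or l2 == 0:
                continue
            # orient consistently before measuring the dihedral
            if np.dot(n1, n2) < 0:
                n2 = -n2
            cosd = np.clip(np.dot(n1 / l1, n2 / l2), -1, 1)
            if np.arccos(cosd) > max_dihedral:
                continue
            old = min(_min_angle(verts[faces[f1]]), _min_angle(verts[faces[f2]]))
            t1 = verts[[a, b, v]]
            t2 = verts[[b, a, u]]
            new = min(_min_angle(t1), _min_angle(t2))
            if new > old + 1e-9:
                faces[f1] = (a, b, v)
                faces[f2] = (b, a, u)
                dirty[f1] = dirty[f2] = True
                edge_set.discard((u, v) if u < v else (v, u))
                edge_set.add(key_new)
                flipped_any = True
        if not flipped_any:
            break
    return TriangleMesh(verts.copy(), faces)


def perturb_er(
    mesh: TriangleMesh,
    target_edge: float,
    iterations: int = 4,
    seed: int = 0,
    feature_angle: float = np.deg2rad(35.0),
) -> TriangleMesh:
    """Explicit isotropic remeshing: split long edges (> 4/3 target), collapse
    short edges (< 4/5 target), flip toward valence 6, tangentially relax and
    project back onto the input surface.

    Feature preserving: vertices on sharp edges (dihedral above
    ``feature_angle``) are kept in place so creases such as the gingival
    margin are not cut across; split midpoints of a crease edge lie exactly
    on the crease line.
    """
    if target_edge <= 0:
        raise ValueError("target_edge must be positive")
    surface = SurfaceIndex(mesh)
    verts = mesh.vertices.copy()
    faces = mesh.faces.copy()
    long_t = 4.0 / 3.0 * target_edge
    short_t = 4.0 / 5.0 * target_edge
    for _ in range(iterations):
        n_before = len(verts)
        verts, faces = _split_long_edges(verts, faces, long_t)
        if len(verts) > n_before:
            # snap split midpoints onto the surface, except midpoints of
            # crease edges which already lie on the crease line
            feat = _feature_vertices(verts, faces, feature_angle)
            new_idx = np.arange(n_before, len(verts))
            movable = np.array([i not in feat for i in new_idx], dtype=bool)
            if movable.any():
                snapped, _, _ = surface.closest(verts[new_idx[movable]])
                verts[new_idx[movable]] = snapped
        feat = _feature_vertices(verts, faces, feature_angle)
        verts, faces = _collapse_short_edges(
            verts, faces, short_t, long_t, surface, frozen=feat
        )
        feat = _feature_vertices(verts, faces, feature_angle)
        faces = _flip_for_valence(verts, faces, frozen=feat)
        feat = _feature_vertices(verts, faces, feature_angle)
        verts = _tangential_relax(verts, faces, surface, frozen=feat)
        verts = _tangential_relax(verts, faces, surface, frozen=feat)
        if len(faces) < 4:
            raise RemeshingError("mesh collapsed below 4 faces")
    return TriangleMesh(verts, faces)


def _feature_vertices(verts, faces, angle: float) -> set:
    """Vertices incident to an edge whose dihedral exceeds ``angle``."""
    efm = _edge_face_map(faces)
    normals = np.cross(
        verts[faces[:, 1]] - verts[faces[:, 0]], verts[faces[:, 2]] - verts[faces[:, 0]]
    )
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.divide(normals, norm, out=np.zeros_like(normals), where=norm > 0)
    cos_t = np.cos(angle)
    out: set = set()
    for (u, v), fs in efm.items():
        if len(fs) != 2:
            continue
        c = float(normals[fs[0]] @ normals[fs[1]])
        if c < cos_t:
            out.add(u)
            out.add(v)
    return out


def _boundary_vertices(faces: np.ndarray) -> np.ndarray:
    efm = _edge_face_map(faces)
    b = set()
    for (u, v), fs in efm.items():
        if len(fs) != 2:
            b.add(u)
            b.add(v)
    return np.array(sorted(b), dtype=np.int64)


def _split_long_edges(verts, faces, long_t):
    efm = _edge_face_map(faces)
    lengths = {e: np.linalg.norm(verts[e[0]] - verts[e[1]]) for e in efm}
    order = sorted(efm, key=lambda e: -lengths[e])
    new_verts = [v for v in verts]
    face_list = [tuple(f) for f in faces]
    dead = set()
    for e in order:
        if lengths[e] <= long_t:
            break
        fs = [f for f in efm[e] if f not in dead]
        if len(fs) != len(efm[e]):
            continue  # an incident face was already rewritten this pass
        u, v = e
        mid = len(new_verts)
        new_verts.append(0.5 * (verts[u] + verts[v]))
        for fi in fs:
            a, b, c = face_list[fi]
            tri = [a, b, c]
            # replace with two faces around the midpoint
            for i in range(3):
                if {tri[i], tri[(i + 1) % 3]} == {u, v}:
                    w = tri[(i + 2) % 3]
                    face_list.append((tri[i], mid, w))
                    face_list.append((mid, tri[(i + 1) % 3], w))
                    break
            dead.add(fi)
    faces_out = np.array(
        [f for i, f in enumerate(face_list) if i not in dead], dtype=np.int64
    )
    return np.array(new_verts), faces_out


def _collapse_short_edges(verts, faces, short_t, long_t, surface=None, frozen=None):
    efm = _edge_face_map(faces)
    boundary = set(_boundary_vertices(faces).tolist())
    if frozen:
        boundary = boundary | frozen
    # vertex -> neighbors
    nbrs: dict[int, set] = {}
    for (u, v) in efm:
        nbrs.setdefault(u, set()).add(v)
        nbrs.setdefault(v, set()).add(u)
    verts = verts.copy()
    alive = np.ones(len(verts), dtype=bool)
    remap = np.arange(len(verts))
    touched = set()
    for (u, v), fs in efm.items():
        if len(fs) != 2:
            continue
        if u in boundary or v in boundary or u in touched or v in touched:
            continue
        if np.linalg.norm(verts[u] - verts[v]) >= short_t:
            continue
        # link condition: shared neighbors must be exactly the two opposite verts
        shared = nbrs[u] & nbrs[v]
        if len(shared) != 2:
            continue
        mid = 0.5 * (verts[u] + verts[v])
        if surface is not None:
            mid = surface.closest(mid[None, :])[0][0]
        # reject if the collapse creates an overlong edge
        far = (nbrs[u] | nbrs[v]) - {u, v}
        if any(np.linalg.norm(verts[w] - mid) > long_t for w in far):
            continue
        verts[u] = mid
        alive[v] = False
        remap[v] = u
        touched.update({u, v} | nbrs[u] | nbrs[v])
    faces2 = remap[faces]
    ok = (
        (faces2[:, 0] != faces2[:, 1])
        & (faces2[:, 1] != faces2[:, 2])
        & (faces2[:, 0] != faces2[:, 2])
    )
    faces2 = faces2[ok]
    # compact vertex array
    used = np.zeros(len(verts), dtype=bool)
    used[faces2.ravel()] = True
    new_index = -np.ones(len(verts), dtype=np.int64)
    new_index[used] = np.arange(used.sum())
    return verts[used], new_index[faces2]


def _flip_for_valence(verts, faces, frozen=None):
    frozen = frozen or set()
    efm = _edge_face_map(faces)
    valence = np.zeros(len(verts), dtype=np.int64)
    for (u, v) in efm:
        valence[u] += 1
        valence[v] += 1
    boundary = set(_boundary_vertices(faces).tolist())
    faces = faces.copy()
    edge_set = set(efm.keys())
    dirty = np.zeros(len(faces), dtype=bool)

    def dev(w, delta=0):
        target = 4 if w in boundary else 6
        return abs(valence[w] + delta - target)

    for (u, v), fs in efm.items():
        if len(fs) != 2:
            continue
        f1, f2 = fs
        if dirty[f1] or dirty[f2]:
            continue
        if u in frozen and v in frozen:
            continue  # never flip a crease edge away
        a = [w for w in faces[f1] if w not in (u, v)][0]
        b = [w for w in faces[f2] if w not in (u, v)][0]
        if a == b:
            continue
        key_new = (a, b) if a < b else (b, a)
        if key_new in edge_set:
            continue
        before = dev(u) + dev(v) + dev(a) + dev(b)
        after = dev(u, -1) + dev(v, -1) + dev(a, +1) + dev(b, +1)
        if after >= before:
            continue
        n1 = np.cross(verts[faces[f1][1]] - verts[faces[f1][0]],
                      verts[faces[f1][2]] - verts[faces[f1][0]])
        t1 = verts[[a, b, v]]
        t2 = verts[[b, a, u]]
        if min(_min_angle(t1), _min_angle(t2)) < np.deg2rad(10):
            continue
        n_new = np.cross(t1[1] - t1[0], t1[2] - t1[0])
        if np.dot(n1, n_new) <= 0 and np.dot(-n1, n_new) <= 0:
            continue
        faces[f1] = (a, b, v)
        faces[f2] = (b, a, u)
        valence[u] -= 1
        valence[v] -= 1
        valence[a] += 1
        valence[b] += 1
        dirty[f1] = dirty[f2] = True
        edge_set.discard((u, v) if u < v else (v, u))
        edge_set.add(key_new)
    return faces


def _tangential_relax(verts, faces, surface: SurfaceIndex, lam: float = 0.5, frozen=None):
    efm = _edge_face_map(faces)
    boundary = set(_boundary_vertices(faces).tolist())
    if frozen:
        boundary = boundary | frozen
    nbr_sum = np.zeros_like(verts)
    nbr_cnt = np.zeros(len(verts))
    for (u, v) in efm:
        nbr_sum[u] += verts[v]
        nbr_sum[v] += verts[u]
        nbr_cnt[u] += 1
        nbr_cnt[v] += 1
    movable = (nbr_cnt > 0).copy()
    if boundary:
        movable[list(boundary)] = False
    centroid = np.divide(
        nbr_sum, nbr_cnt[:, None], out=verts.copy(), where=nbr_cnt[:, None] > 0
    )
    out = verts.copy()
    out[movable] = verts[movable] + lam * (centroid[movable] - verts[movable])
    snapped, _, _ = surface.closest(out[movable])
    out[movable] = snapped
    return out
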