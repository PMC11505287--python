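"""Mesh and label data model, file I/O and geometry primitives.

The segmentation task is defined over a triangle mesh ``M = (V, F)`` of a
single dental arch (maxilla or mandible) together with a per-face labeling
``g : F -> C`` where ``C`` holds sixteen tooth classes (two quadrants, eight
tooth types each) and a gingiva class ``G``.  No manifoldness, closure or
resolution assumptions are made about the mesh; degenerate faces are dropped
at load time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import trimesh

log = logging.getLogger(__name__)

# Anatomical order used everywhere: left third molar to left central incisor,
# then right central incisor to right third molar, gingiva last.
TOOTH_CODES: tuple[str, ...] = tuple(
    [f"L{i}" for i in range(8, 0, -1)] + [f"R{i}" for i in range(1, 9)] + ["G"]
)
CODE_TO_INDEX: dict[str, int] = {c: i for i, c in enumerate(TOOTH_CODES)}
GINGIVA_INDEX = 16
N_TOOTH_CLASSES = 16


@dataclass(frozen=True, order=True)
class ToothClass:
    """One of 17 face classes: a tooth (``L8``..``L1``, ``R1``..``R8``) or gingiva ``G``.

    ``index`` runs 0..16 in anatomical order with gingiva at 16.
    """

    index: int

    def __post_init__(self) -> None:
        if not 0 <= self.index <= GINGIVA_INDEX:
            raise ValueError(f"tooth class index out of range: {self.index}")

    @classmethod
    def from_code(cls, code: str) -> "ToothClass":
        try:
            return cls(CODE_TO_INDEX[code])
        except KeyError:
            raise ValueError(f"unknown tooth class code: {code!r}") from None

    @property
    def code(self) -> str:
        return TOOTH_CODES[self.index]

    @property
    def is_gingiva(self) -> bool:
        return self.index == GINGIVA_INDEX

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ToothClass({self.code})"


GINGIVA = ToothClass(GINGIVA_INDEX)
ALL_TEETH: tuple[ToothClass, ...] = tuple(ToothClass(i) for i in range(N_TOOTH_CLASSES))


class MeshValidationError(ValueError):
    pass


@dataclass
class TriangleMesh:
    """Raw triangle soup: ``vertices`` (n,3) float64 mm, ``faces`` (m,3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) < 1:
            raise MeshValidationError("mesh must have at least one face")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshValidationError("face index out of vertex range")
        f = self.faces
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise MeshValidationError("mesh contains degenerate faces")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of per-face vertex positions."""
        return self.vertices[self.faces]

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())


@dataclass
class FaceLabeling:
    """Per-face class assignment, stored as an (m,) int8/int16 index array."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int16).ravel()
        if len(self.indices) == 0:
            raise MeshValidationError("labeling must cover at least one face")
        if self.indices.min() < 0 or self.indices.max() > GINGIVA_INDEX:
            raise MeshValidationError("label index out of class range")

    @classmethod
    def from_codes(cls, codes: Sequence[str]) -> "FaceLabeling":
        return cls(np.array([CODE_TO_INDEX[c] for c in codes], dtype=np.int16))

    def __len__(self) -> int:
        return len(self.indices)

    def codes(self) -> list[str]:
        return [TOOTH_CODES[i] for i in self.indices]

    def present_teeth(self) -> list[ToothClass]:
        """Tooth classes (gingiva excluded) with at least one face."""
        present = np.unique(self.indices)
        return [ToothClass(int(i)) for i in present if i != GINGIVA_INDEX]

    def faces_of(self, cls: ToothClass) -> np.ndarray:
        return np.flatnonzero(self.indices == cls.index)


# ---------------------------------------------------------------------------
# I/O


def read_mesh(path: str | Path) -> TriangleMesh:
    """Load an STL/PLY/OBJ mesh, dropping degenerate faces.

    Vertex/face storage order is preserved (``process=False``): per-face
    annotation sidecars index faces in storage order.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load(str(path), process=False, force="mesh")
    except Exception as exc:  # parse failure
        raise IOError(f"cannot read mesh {path}: {exc}") from exc
    vertices = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if faces.size == 0:
        raise IOError(f"no faces in mesh file: {path}")
    keep = _nondegenerate_mask(vertices, faces)
    dropped = int(len(faces) - keep.sum())
    if dropped:
        log.warning("dropped %d degenerate face(s) while reading %s", dropped, path)
    faces = faces[keep]
    if len(faces) == 0:
        raise MeshValidationError(f"all faces degenerate in {path}")
    return TriangleMesh(vertices, faces)


def _nondegenerate_mask(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    distinct = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    tri = vertices[np.clip(faces, 0, len(vertices) - 1)]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area2 = np.linalg.norm(cross, axis=1)
    return distinct & (area2 > 0.0)


def write_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    """Write STL/PLY/OBJ inferred from the suffix."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))


def write_labels(labeling: FaceLabeling, path: str | Path, mesh: TriangleMesh | None = None) -> None:
    """Write the label sidecar: one class code per line, line i = face i."""
    if mesh is not None and len(labeling) != mesh.n_faces:
        raise MeshValidationError(
            f"labeling length {len(labeling)} != face count {mesh.n_faces}"
        )
    Path(path).write_text("\n".join(labeling.codes()) + "\n")


def read_labels(path: str | Path, mesh: TriangleMesh | None = None) -> FaceLabeling:
    """Read a label sidecar; accepts an optional JSON-header variant.

    A first line starting with ``{`` is parsed as a JSON header (may carry a
    mesh checksum) and skipped.
    """
    lines = Path(path).read_text().splitlines()
    if lines and lines[0].lstrip().startswith("{"):
        json.loads(lines[0])  # validate header
        lines = lines[1:]
    codes = [ln.strip() for ln in lines if ln.strip()]
    for c in codes:
        if c not in CODE_TO_INDEX:
            raise ValueError(f"unknown class code in {path}: {c!r}")
    labeling = FaceLabeling.from_codes(codes)
    if mesh is not None and len(labeling) != mesh.n_faces:
        raise MeshValidationError(
            f"label file has {len(labeling)} rows but mesh has {mesh.n_faces} faces"
        )
    return labeling


# ---------------------------------------------------------------------------
# Geometry primitives


def face_areas(mesh: TriangleMesh) -> np.ndarray:
    """Per-face areas in mm^2 (half cross-product norm)."""
    tri = mesh.triangles()
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


def face_normals(mesh: TriangleMesh) -> np.ndarray:
    """Unit face normals; zero vector for (numerically) degenerate faces."""
    tri = mesh.triangles()
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(cross, axis=1, keepdims=True)
    return np.divide(cross, norm, out=np.zeros_like(cross), where=norm > 0)


def face_adjacency(mesh: TriangleMesh) -> list[np.ndarray]:
    """Edge-adjacency: for each face the faces sharing an edge with it.

    Symmetric; non-manifold edges (more than two incident faces) connect all
    incident faces pairwise.
    """
    pairs = face_adjacency_pairs(mesh)
    neighbors: list[list[int]] = [[] for _ in range(mesh.n_faces)]
    for a, b in pairs:
        neighbors[a].append(b)
        neighbors[b].append(a)
    return [np.array(sorted(set(n)), dtype=np.int64) for n in neighbors]


def face_adjacency_pairs(mesh: TriangleMesh) -> np.ndarray:
    """(k, 2) array of unordered face pairs sharing an edge."""
    f = mesh.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    owner = np.tile(np.arange(len(f)), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges, owner = edges[order], owner[order]
    same = np.all(edges[1:] == edges[:-1], axis=1)
    # group runs of identical edges; pair all owners within a run
    pairs: list[tuple[int, int]] = []
    i = 0
    n = len(edges)
    while i < n:
        j = i + 1
        while j < n and same[j - 1]:
            j += 1
        if j - i > 1:
            group = owner[i:j]
            for a in range(len(group)):
                for b in range(a + 1, len(group)):
                    pairs.append((int(group[a]), int(group[b])))
        i = j
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.array(pairs, dtype=np.int64)


def label_boundary_vertices(
    mesh: TriangleMesh, labeling: FaceLabeling, cls: ToothClass
) -> np.ndarray:
    """Positions of vertices on the label boundary of ``cls``.

    A vertex qualifies when it is incident to at least one face labeled
    ``cls`` and at least one face labeled differently.  Returns an (k, 3)
    array (k may be 0).
    """
    if len(labeling) != mesh.n_faces:
        raise MeshValidationError("labeling does not match mesh")
    in_cls = labeling.indices == cls.index
    verts_in = np.zeros(mesh.n_vertices, dtype=bool)
    verts_out = np.zeros(mesh.n_vertices, dtype=bool)
    verts_in[mesh.faces[in_cls].ravel()] = True
    verts_out[mesh.faces[~in_cls].ravel()] = True
    return mesh.vertices[verts_in & verts_out]
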