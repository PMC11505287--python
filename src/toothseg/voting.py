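"""Unprojection of 2D mask sequences to mesh faces, multi-view certainty,
region voting and connected-component cleanup.

Independent per-tooth segmentation can (1) assign one face to several
classes and (2) produce regions with satellite components.  Region voting
resolves (1): each face goes to the class with the highest *multi-view
certainty* — the fraction of views in which the face was first-hit by a
positive mask ray among the views where it was visible at all — or to
gingiva when all certainties are zero.  Connected-component cleanup resolves
(2): per class only the largest component survives; faces of discarded
components move to their next-best class whose retained region accepts them
(edge adjacency), else gingiva.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .mesh import (
    GINGIVA_INDEX,
    N_TOOTH_CLASSES,
    FaceLabeling,
    TriangleMesh,
    face_adjacency_pairs,
    face_areas,
)
from .views import RenderRecord


@dataclass
class CertaintyTable:
    """Dense per-(face, tooth-class) multi-view certainty.

    hit/visible counts are per *view* (a face hit by many pixels in one view
    counts once).  ``certainty = hits/visible`` where visible > 0, else 0.
    """

    hit_counts: np.ndarray  # (16, n_faces) int
    visible_counts: np.ndarray  # (16, n_faces) int

    def __post_init__(self) -> None:
        if self.hit_counts.shape != self.visible_counts.shape:
            raise ValueError("count shapes differ")
        if np.any(self.hit_counts > self.visible_counts):
            raise ValueError("hit count exceeds visible count")

    @property
    def certainty(self) -> np.ndarray:
        vis = self.visible_counts
        return np.divide(
            self.hit_counts,
            vis,
            out=np.zeros(vis.shape, dtype=np.float64),
            where=vis > 0,
        )


def unproject_masks(
    masks: np.ndarray, records: list[RenderRecord], n_faces: int
) -> tuple[np.ndarray, np.ndarray]:
    """Cast mask-positive pixels back to faces via the first-hit tables.

    masks: (n_views, H, W) binary.  Returns (face_set, hit_counts) where
    ``face_set`` is a sorted array of face indices hit in >=1 view and
    ``hit_counts[f]`` is the number of distinct views contributing face f.
    """
    masks = np.asarray(masks)
    if len(masks) != len(records):
        raise ValueError("masks and records differ in view count")
    hits = np.zeros(n_faces, dtype=np.int64)
    for m, rec in zip(masks, records):
        if m.shape != rec.first_hit.shape:
            raise ValueError("mask/record resolution mismatch")
        f = rec.first_hit[(m > 0) & (rec.first_hit >= 0)]
        if len(f):
            hits[np.unique(f)] += 1
    return np.flatnonzero(hits), hits


def visibility_counts(records: list[RenderRecord], n_faces: int) -> np.ndarray:
    """Number of views in which each face is first-hit visible."""
    vis = np.zeros(n_faces, dtype=np.int64)
    for rec in records:
        vis[rec.visible_faces] += 1
    return vis


def build_certainty(
    per_tooth_hits: dict[int, np.ndarray],
    per_tooth_visible: dict[int, np.ndarray],
    n_faces: int,
) -> CertaintyTable:
    """Assemble the certainty table from per-tooth hit and visibility counts.

    Each tooth's visibility denominator comes from its own view geometry.
    Teeth not processed (missing) keep all-zero rows.
    """
    hit = np.zeros((N_TOOTH_CLASSES, n_faces), dtype=np.int64)
    vis = np.zeros((N_TOOTH_CLASSES, n_faces), dtype=np.int64)
    for slot, h in per_tooth_hits.items():
        hit[slot] = h
        vis[slot] = per_tooth_visible[slot]
    # a ray can only hit a visible face, but guard against inconsistent input
    return CertaintyTable(np.minimum(hit, vis), vis)


def region_voting(table: CertaintyTable) -> FaceLabeling:
    """Assign each face to its argmax-certainty class (ties -> lower class
    index), or gingiva when every certainty is zero."""
    cert = table.certainty
    best = np.argmax(cert, axis=0)  # first max = lowest class index
    best_val = cert[best, np.arange(cert.shape[1])]
    labels = np.where(best_val > 0, best, GINGIVA_INDEX).astype(np.int16)
    return FaceLabeling(labels)


def cca_cleanup(
    mesh: TriangleMesh, labeling: FaceLabeling, table: CertaintyTable
) -> FaceLabeling:
    """Keep only the largest connected component of each tooth class.

    Component ties break by larger total area, then lowest face index.
    Faces of discarded components are reassigned to their next-best-certainty
    class whose retained region is edge-adjacent to them, else gingiva.
    """
    pairs = face_adjacency_pairs(mesh)
    areas = face_areas(mesh)
    labels = labeling.indices.copy()
    cert = table.certainty

    # CSR adjacency for O(1) neighbor lookups
    n = mesh.n_faces
    if len(pairs):
        rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
        cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
        adj = coo_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)).tocsr()
    else:
        adj = coo_matrix((n, n), dtype=np.int8).tocsr()

    def neighbors_of(f: int) -> np.ndarray:
        return adj.indices[adj.indptr[f] : adj.indptr[f + 1]]

    discarded: list[int] = []
    retained_mask = np.zeros((N_TOOTH_CLASSES, mesh.n_faces), dtype=bool)
    for cls_idx in np.unique(labels):
        if cls_idx == GINGIVA_INDEX:
            continue
        members = np.flatnonzero(labels == cls_idx)
        comp = _components_of(members, pairs, mesh.n_faces)
        n_comp = comp.max() + 1
        if n_comp == 1:
            retained_mask[cls_idx, members] = True
            continue
        sizes = np.bincount(comp, minlength=n_comp)
        comp_area = np.bincount(comp, weights=areas[members], minlength=n_comp)
        first_face = np.full(n_comp, mesh.n_faces, dtype=np.int64)
        np.minimum.at(first_face, comp, members)
        order = sorted(
            range(n_comp), key=lambda c: (-sizes[c], -comp_area[c], first_face[c])
        )
        keep = order[0]
        retained_mask[cls_idx, members[comp == keep]] = True
        discarded.extend(members[comp != keep].tolist())

    for f in sorted(discarded):
        candidates = np.argsort(-cert[:, f], kind="stable")
        new_label = GINGIVA_INDEX
        for c in candidates:
            if cert[c, f] <= 0:
                continue
            if retained_mask[c, neighbors_of(f)].any():
                new_label = int(c)
                break
        labels[f] = new_label
        if new_label != GINGIVA_INDEX:
            retained_mask[new_label, f] = True
    return FaceLabeling(labels)


def _components_of(members: np.ndarray, pairs: np.ndarray, n_faces: int) -> np.ndarray:
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
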