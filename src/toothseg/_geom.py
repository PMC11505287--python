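"""Point-to-surface queries used across the package.

Closest-point queries go through a k-d tree on face centroids followed by an
exact point-triangle distance over the candidate faces; with enough
candidates this is exact for the meshes handled here and avoids any
dependency on spatial-index extensions.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .mesh import TriangleMesh


def closest_point_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle for each query point.

    points: (n, 3); tri: (n, 3, 3).  Returns (n, 3).  Vectorized version of
    the standard region-classification algorithm (Ericson).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    p = points
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    result = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex region A
    m = (d1 <= 0) & (d2 <= 0)
    result[m] = a[m]
    done |= m

    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    m = ~done & (d3 >= 0) & (d4 <= d3)
    result[m] = b[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = np.where(np.abs(d1 - d3) > 0, d1 - d3, 1.0)
    v = d1 / denom
    result[m] = a[m] + v[m, None] * ab[m]
    done |= m

    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    m = ~done & (d6 >= 0) & (d5 <= d6)
    result[m] = c[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = np.where(np.abs(d2 - d6) > 0, d2 - d6, 1.0)
    w = d2 / denom
    result[m] = a[m] + w[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    denom = (d4 - d3) + (d5 - d6)
    denom = np.where(np.abs(denom) > 0, denom, 1.0)
    w = (d4 - d3) / denom
    result[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    denom = np.where(np.abs(denom) > 0, denom, 1.0)
    v = vb / denom
    w = vc / denom
    result[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return result


class SurfaceIndex:
    """Reusable closest-point / nearest-face index for one mesh."""

    def __init__(self, mesh: TriangleMesh, k: int = 16):
        self.mesh = mesh
        self.tri = mesh.triangles()
        self.centroids = self.tri.mean(axis=1)
        self.tree = cKDTree(self.centroids)
        self.k = min(k, mesh.n_faces)

    def closest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest_points, distances, face_indices) for (n,3) queries."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        _, cand = self.tree.query(points, k=self.k)
        cand = np.atleast_2d(cand)
        n, k = cand.shape
        flat_pts = np.repeat(points, k, axis=0)
        flat_tri = self.tri[cand.ravel()]
        cp = closest_point_on_triangles(flat_pts, flat_tri).reshape(n, k, 3)
        d = np.linalg.norm(cp - points[:, None, :], axis=2)
        best = np.argmin(d, axis=1)
        rows = np.arange(n)
        return cp[rows, best], d[rows, best], cand[rows, best]


def surface_distance_samples(
    mesh_a: TriangleMesh, mesh_b: TriangleMesh, n_samples: int = 4000, seed: int = 0
) -> np.ndarray:
    """Distances from points sampled uniformly by area on A to surface B."""
    rng = np.random.default_rng(seed)
    tri = mesh_a.triangles()
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    probs = areas / areas.sum()
    idx = rng.choice(len(tri), size=n_samples, p=probs)
    u = rng.random(n_samples)
    v = rng.random(n_samples)
    flip = u + v > 1
    u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
    t = tri[idx]
    pts = t[:, 0] + u[:, None] * (t[:, 1] - t[:, 0]) + v[:, None] * (t[:, 2] - t[:, 0])
    _, d, _ = SurfaceIndex(mesh_b).closest(pts)
    return d
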