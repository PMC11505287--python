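"""Occlusion alignment: rigid registration of a scan into the canonical
upright, origin-centered coordinate system using per-tooth landmarks.

Each tooth carries a mesial and a distal landmark on its occlusal surface;
missing teeth are encoded with an infinity sentinel.  Because correspondence
is known (by tooth slot and landmark role), the least-squares rigid transform
is closed-form (Kabsch / orthogonal Procrustes) — an iterative
closest-point matching step would be redundant on known correspondences and
yields the identical solution there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .arch import CROWN_HEIGHTS_MM, CROWN_WIDTHS_MM, arch_point, arch_tangent, tooth_slot_parameters
from .mesh import TriangleMesh

SENTINEL = np.inf


class AlignmentError(ValueError):
    pass


@dataclass
class LandmarkSet:
    """16 (mesial, distal) landmark pairs in mm, ordered L8..L1, R1..R8.

    ``mesial``/``distal`` are (16, 3) arrays; a missing tooth has +inf in all
    six coordinates.
    """

    mesial: np.ndarray
    distal: np.ndarray

    def __post_init__(self) -> None:
        self.mesial = np.asarray(self.mesial, dtype=np.float64).reshape(16, 3)
        self.distal = np.asarray(self.distal, dtype=np.float64).reshape(16, 3)
        mes_fin = np.isfinite(self.mesial).all(axis=1)
        dis_fin = np.isfinite(self.distal).all(axis=1)
        if np.any(mes_fin != dis_fin):
            raise AlignmentError("mesial/distal must be both finite or both sentinel")

    @property
    def present(self) -> np.ndarray:
        """(16,) bool mask of teeth with finite landmarks."""
        return np.isfinite(self.mesial).all(axis=1)

    def points(self) -> np.ndarray:
        """(32, 3) stacked [mesial_0, distal_0, mesial_1, ...] incl. sentinels."""
        return np.stack([self.mesial, self.distal], axis=1).reshape(32, 3)

    def finite_points(self) -> np.ndarray:
        pts = self.points()
        return pts[np.isfinite(pts).all(axis=1)]

    def tooth_pair(self, slot: int) -> tuple[np.ndarray, np.ndarray]:
        return self.mesial[slot], self.distal[slot]

    def transformed(self, xf: "RigidTransform", scale: float = 1.0) -> "LandmarkSet":
        def _map(p):
            out = np.full_like(p, np.inf)
            fin = np.isfinite(p).all(axis=1)
            out[fin] = scale * (p[fin] @ xf.rotation.T) + xf.translation
            return out

        return LandmarkSet(_map(self.mesial), _map(self.distal))


@dataclass
class RigidTransform:
    """Proper rigid transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise AlignmentError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise AlignmentError("rotation determinant is not +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.rotation.T + self.translation

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


def fit_rigid_alignment(observed: LandmarkSet, reference: LandmarkSet) -> RigidTransform:
    """Least-squares rigid transform mapping observed landmarks onto reference.

    Correspondence is by tooth slot and mesial/distal role; only teeth present
    in both sets contribute.  Kabsch with the standard reflection guard.
    """
    both = observed.present & reference.present
    if both.sum() < 2:
        raise AlignmentError(
            f"need >=2 shared teeth (4 landmark pairs), got {int(both.sum())}"
        )
    src = np.concatenate([observed.mesial[both], observed.distal[both]])
    dst = np.concatenate([reference.mesial[both], reference.distal[both]])
    return kabsch(src, dst)


def kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Closed-form rigid fit R, t minimizing ||R src + t - dst||^2."""
    if len(src) < 3:
        raise AlignmentError("need at least 3 point pairs")
    src_c = src.mean(axis=0)
    dst_c = dst.mean(axis=0)
    h = (src - src_c).T @ (dst - dst_c)
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise AlignmentError("degenerate (collinear) landmark configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = dst_c - rot @ src_c
    return RigidTransform(rot, t)


def apply_transform(mesh: TriangleMesh, xf: RigidTransform) -> TriangleMesh:
    """Transform every vertex, faces unchanged."""
    return TriangleMesh(xf.apply_points(mesh.vertices), mesh.faces.copy())


def canonical_reference(
    arch_width: float = 64.0, arch_depth: float = 54.0
) -> LandmarkSet:
    """Shipped reference landmark template in canonical pose.

    A symmetric full-arch layout: tooth slots along a parabolic arch in the
    occlusal plane, mesial/distal landmarks offset along the arch tangent,
    z at the occlusal (crown-top) level.  Upright along z, centered so the
    x/y mean of all landmarks is at the origin.
    """
    t_slots = tooth_slot_parameters(arch_width, arch_depth)
    centers = arch_point(t_slots, arch_width, arch_depth)
    tangents = arch_tangent(t_slots, arch_width, arch_depth)
    types = np.array(list(range(8, 0, -1)) + list(range(1, 9)))  # L8..L1,R1..R8
    widths = CROWN_WIDTHS_MM[types - 1]
    heights = CROWN_HEIGHTS_MM[types - 1]
    semi_axis = 0.5 * widths - 0.25  # crown footprint semi-axis (mesiodistal)
    offs = tangents * (0.7 * semi_axis)[:, None]
    # mesial = toward the midline: -tangent on the right quadrant, +tangent on the left
    toward_mid = np.where(np.arange(16)[:, None] < 8, 1.0, -1.0)
    mesial = centers + toward_mid * offs
    distal = centers - toward_mid * offs
    # z at the landmark offset on the paraboloid crown dome (rho = 0.7)
    z_land = heights * (1.0 - 0.7**2)
    mesial[:, 2] = z_land
    distal[:, 2] = z_land
    all_pts = np.concatenate([mesial, distal])
    shift = all_pts.mean(axis=0)
    shift[2] = 0.0  # keep z at the occlusal level above the base plane
    return LandmarkSet(mesial - shift, distal - shift)


# ---------------------------------------------------------------------------
# Sidecar I/O: "<mesh>.landmarks.json"


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    """16 entries of {"mesial": [x,y,z], "distal": [...]} or null (missing)."""
    entries = []
    for i in range(16):
        if landmarks.present[i]:
            entries.append(
                {
                    "mesial": [float(v) for v in landmarks.mesial[i]],
                    "distal": [float(v) for v in landmarks.distal[i]],
                }
            )
        else:
            entries.append(None)
    Path(path).write_text(json.dumps(entries, indent=1))


def read_landmarks(path: str | Path) -> LandmarkSet:
    entries = json.loads(Path(path).read_text())
    if len(entries) != 16:
        raise AlignmentError(f"landmark file must have 16 entries, got {len(entries)}")
    mesial = np.full((16, 3), np.inf)
    distal = np.full((16, 3), np.inf)
    for i, e in enumerate(entries):
        if e is None:
            continue
        m = [np.inf if str(v) == "inf" else float(v) for v in e["mesial"]]
        d = [np.inf if str(v) == "inf" else float(v) for v in e["distal"]]
        mesial[i] = m
        distal[i] = d
    return LandmarkSet(mesial, distal)
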