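"""Per-tooth camera trajectory and orthographic depth/normal rendering.

For each tooth, cameras sit on a sphere of fixed radius around the mean of
the tooth's two landmarks and follow a spiral trajectory: zenith grows
linearly from 0 to ``max_zenith`` while azimuth advances by a constant step
(golden angle by default), every camera looking at the tooth center.  Each
view is rendered with an orthographic camera into a depth map (0 =
background/infinity, larger = nearer), a screen-space normal map, and a
pixel -> first-hit-face table used later for unprojection and multi-view
certainty.

Rendering is a z-buffer triangle rasterizer over pixel centers, which for an
orthographic camera produces exactly the nearest ray-triangle intersection
per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .mesh import TriangleMesh, face_normals

GOLDEN_ANGLE = np.deg2rad(137.50776405003785)


class MissingToothError(ValueError):
    pass


@dataclass
class CameraPose:
    """Orthographic camera: viewport is a square of half-width ``half_extent``
    mm centered on the view axis; depth measured from the camera position."""

    position: np.ndarray
    look_at: np.ndarray
    up: np.ndarray
    half_extent: float = 10.0
    depth_range: float = 40.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64).reshape(3)
        self.look_at = np.asarray(self.look_at, dtype=np.float64).reshape(3)
        self.up = np.asarray(self.up, dtype=np.float64).reshape(3)
        if np.allclose(self.position, self.look_at):
            raise ValueError("camera position equals look_at")
        if self.half_extent <= 0 or self.depth_range <= 0:
            raise ValueError("half_extent and depth_range must be positive")
        d = self.view_dir
        if abs(np.dot(d, self.up / np.linalg.norm(self.up))) > 1 - 1e-12:
            raise ValueError("up vector parallel to view direction")

    @property
    def view_dir(self) -> np.ndarray:
        d = self.look_at - self.position
        return d / np.linalg.norm(d)

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(right, up, toward-camera) orthonormal camera axes."""
        d = self.view_dir
        r = np.cross(d, self.up)
        r /= np.linalg.norm(r)
        u = np.cross(r, d)
        return r, u, -d


@dataclass
class ViewMaps:
    """depth: (H,W) in [0,1], 0 = no hit; normal: (3,H,W) camera-space."""

    depth: np.ndarray
    normal: np.ndarray


@dataclass
class RenderRecord:
    """first_hit: (H,W) int32 face indices, -1 = background."""

    first_hit: np.ndarray

    @property
    def visible_faces(self) -> np.ndarray:
        vals = np.unique(self.first_hit)
        return vals[vals >= 0]


@dataclass
class ViewSequence:
    poses: list[CameraPose]
    maps: list[ViewMaps]
    records: list[RenderRecord]

    def __len__(self) -> int:
        return len(self.poses)


def _up_for_direction(view_dir: np.ndarray) -> np.ndarray:
    """Global +y projected off the view axis; +x fallback when degenerate."""
    up = np.array([0.0, 1.0, 0.0])
    proj = up - np.dot(up, view_dir) * view_dir
    if np.linalg.norm(proj) < 1e-9:
        up = np.array([1.0, 0.0, 0.0])
        proj = up - np.dot(up, view_dir) * view_dir
    return proj / np.linalg.norm(proj)


def sample_views(
    landmarks_of_tooth: tuple[np.ndarray, np.ndarray],
    n: int = 49,
    radius: float = 15.0,
    max_zenith: float = np.deg2rad(60.0),
    azimuth_step: float = GOLDEN_ANGLE,
    half_extent: float = 10.0,
    depth_range: float = 40.0,
) -> list[CameraPose]:
    """Spiral camera trajectory around one tooth.

    Pose 0 sits ``radius`` mm straight above the tooth center (the mean of
    the mesial and distal landmarks); pose i sits on the same sphere at
    zenith ``max_zenith * i/(n-1)`` and azimuth ``i * azimuth_step``, always
    looking at the center.
    """
    mesial, distal = (np.asarray(p, dtype=np.float64) for p in landmarks_of_tooth)
    if not (np.isfinite(mesial).all() and np.isfinite(distal).all()):
        raise MissingToothError("tooth has sentinel landmarks")
    if n < 1:
        raise ValueError("need at least one view")
    center = 0.5 * (mesial + distal)
    poses = []
    for i in range(n):
        zen = 0.0 if n == 1 else max_zenith * i / (n - 1)
        azi = i * azimuth_step
        offset = radius * np.array(
            [np.sin(zen) * np.cos(azi), np.sin(zen) * np.sin(azi), np.cos(zen)]
        )
        pos = center + offset
        view_dir = (center - pos) / radius
        poses.append(
            CameraPose(
                position=pos,
                look_at=center,
                up=_up_for_direction(view_dir),
                half_extent=half_extent,
                depth_range=depth_range,
            )
        )
    return poses


@njit(cache=False)
def _rasterize(v_cam, faces, H, W, half_extent, depth_range):  # pragma: no cover
    """Z-buffer rasterization in camera coordinates.

    v_cam: (n,3) with x right, y up, z = distance from camera along the view
    axis.  Pixel (row i, col j) center maps to x = (j+0.5)/W*2he - he,
    y = he - (i+0.5)/H*2he (row 0 at the top, +up).
    """
    tbuf = np.full((H, W), np.inf)
    fidx = np.full((H, W), -1, dtype=np.int32)
    sx = W / (2.0 * half_extent)
    sy = H / (2.0 * half_extent)
    for k in range(faces.shape[0]):
        i0, i1, i2 = faces[k, 0], faces[k, 1], faces[k, 2]
        x0 = (v_cam[i0, 0] + half_extent) * sx - 0.5
        y0 = (half_extent - v_cam[i0, 1]) * sy - 0.5
        x1 = (v_cam[i1, 0] + half_extent) * sx - 0.5
        y1 = (half_extent - v_cam[i1, 1]) * sy - 0.5
        x2 = (v_cam[i2, 0] + half_extent) * sx - 0.5
        y2 = (half_extent - v_cam[i2, 1]) * sy - 0.5
        z0, z1, z2 = v_cam[i0, 2], v_cam[i1, 2], v_cam[i2, 2]
        jmin = max(0, int(np.ceil(min(x0, x1, x2))))
        jmax = min(W - 1, int(np.floor(max(x0, x1, x2))))
        imin = max(0, int(np.ceil(min(y0, y1, y2))))
        imax = min(H - 1, int(np.floor(max(y0, y1, y2))))
        if jmin > jmax or imin > imax:
            continue
        d = (y1 - y2) * (x0 - x2) + (x2 - x1) * (y0 - y2)
        if d == 0.0:
            continue
        inv = 1.0 / d
        for i in range(imin, imax + 1):
            for j in range(jmin, jmax + 1):
                w0 = ((y1 - y2) * (j - x2) + (x2 - x1) * (i - y2)) * inv
                w1 = ((y2 - y0) * (j - x2) + (x0 - x2) * (i - y2)) * inv
                w2 = 1.0 - w0 - w1
                if w0 < -1e-12 or w1 < -1e-12 or w2 < -1e-12:
                    continue
                t = w0 * z0 + w1 * z1 + w2 * z2
                if t <= 0.0 or t >= depth_range:
                    continue
                if t < tbuf[i, j]:
                    tbuf[i, j] = t
                    fidx[i, j] = k
    return tbuf, fidx


def render_view(
    mesh: TriangleMesh, pose: CameraPose, resolution: int = 256
) -> tuple[ViewMaps, RenderRecord]:
    """Render one orthographic view.

    Depth = 1 - t/depth_range for the nearest hit at distance t (nearer =>
    larger), 0 on background.  Normals are per-face (flat shading), rotated
    into camera space and flipped per pixel so the component toward the
    camera is non-negative; zero vector on background.
    """
    H = W = int(resolution)
    r, u, zc = pose.basis()
    rel = mesh.vertices - pose.position
    v_cam = np.column_stack([rel @ r, rel @ u, rel @ pose.view_dir])

    # cull faces fully outside the viewport or depth range
    tri_cam = v_cam[mesh.faces]
    he = pose.half_extent
    keep = (
        (tri_cam[:, :, 0].min(axis=1) <= he)
        & (tri_cam[:, :, 0].max(axis=1) >= -he)
        & (tri_cam[:, :, 1].min(axis=1) <= he)
        & (tri_cam[:, :, 1].max(axis=1) >= -he)
        & (tri_cam[:, :, 2].max(axis=1) > 0)
        & (tri_cam[:, :, 2].min(axis=1) < pose.depth_range)
    )
    kept = np.flatnonzero(keep)
    depth = np.zeros((H, W), dtype=np.float64)
    normal = np.zeros((3, H, W), dtype=np.float64)
    first_hit = np.full((H, W), -1, dtype=np.int32)
    if len(kept):
        tbuf, fidx = _rasterize(
            v_cam, mesh.faces[kept], H, W, he, pose.depth_range
        )
        hit = fidx >= 0
        first_hit[hit] = kept[fidx[hit]]
        depth[hit] = 1.0 - tbuf[hit] / pose.depth_range
        n_world = face_normals(mesh)
        n_cam = np.column_stack([n_world @ r, n_world @ u, n_world @ zc])
        flip = n_cam[:, 2] < 0
        n_cam[flip] = -n_cam[flip]
        normal[:, hit] = n_cam[first_hit[hit]].T
    return ViewMaps(depth, normal), RenderRecord(first_hit)


def render_sequence(
    mesh: TriangleMesh, poses: list[CameraPose], resolution: int = 256
) -> ViewSequence:
    maps, records = [], []
    for pose in poses:
        vm, rr = render_view(mesh, pose, resolution)
        maps.append(vm)
        records.append(rr)
    return ViewSequence(poses, maps, records)


def sequence_input_array(seq: ViewSequence, i_tt: float) -> np.ndarray:
    """Stack a view sequence into the network input (n, 5, H, W) float32:
    channels = depth, normal xyz, constant tooth-type signal."""
    n = len(seq)
    H, W = seq.maps[0].depth.shape
    out = np.empty((n, 5, H, W), dtype=np.float32)
    for i, vm in enumerate(seq.maps):
        out[i, 0] = vm.depth
        out[i, 1:4] = vm.normal
        out[i, 4] = i_tt
    return out


def dump_view_png(maps: ViewMaps, path_prefix: str) -> None:
    """Optional debug dump: 16-bit depth PNG and 8-bit normal PNG."""
    from PIL import Image

    d16 = (np.clip(maps.depth, 0, 1) * 65535).astype(np.uint16)
    Image.fromarray(d16, mode="I;16").save(f"{path_prefix}_depth.png")
    n8 = ((maps.normal.transpose(1, 2, 0) * 0.5 + 0.5) * 255).astype(np.uint8)
    Image.fromarray(n8).save(f"{path_prefix}_normal.png")
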