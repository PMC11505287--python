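"""Parametric dental-arch layout shared by the synthetic generator and the
canonical landmark template.

The arch is a parabola in the z=0 plane, symmetric about x=0, with the
incisors at the anterior apex and the third molars at the posterior ends.
Tooth slots are placed by arc length according to typical mesiodistal crown
widths, mirrored exactly between the left and right quadrants so the layout
is symmetric to machine precision.
"""

from __future__ import annotations

import numpy as np

# Typical mesiodistal crown widths in mm, tooth types 1 (central incisor)
# .. 8 (third molar).  Rounded averages over upper/lower arches.
CROWN_WIDTHS_MM: np.ndarray = np.array([8.5, 6.5, 7.5, 7.0, 6.8, 10.0, 9.5, 8.8])

# Typical exposed crown heights above the gingival margin, in mm, types 1..8.
CROWN_HEIGHTS_MM: np.ndarray = np.array([5.0, 4.5, 5.5, 5.0, 4.8, 4.5, 4.2, 4.0])

INTER_TOOTH_GAP_MM = 0.6


def arch_point(t: np.ndarray | float, width: float, depth: float) -> np.ndarray:
    """Arch curve P(t), t in [-1, 1]; t<0 left quadrant, t=0 midline.

    Anterior apex at (0, depth), posterior ends at (+-width/2, 0).
    """
    t = np.asarray(t, dtype=np.float64)
    x = 0.5 * width * t
    y = depth * (1.0 - t * t)
    return np.stack([x, y, np.zeros_like(x)], axis=-1)


def arch_tangent(t: np.ndarray | float, width: float, depth: float) -> np.ndarray:
    """Unit tangent dP/dt, pointing from left (t=-1) toward right (t=+1)."""
    t = np.asarray(t, dtype=np.float64)
    dx = np.full_like(t, 0.5 * width)
    dy = -2.0 * depth * t
    tang = np.stack([dx, dy, np.zeros_like(t)], axis=-1)
    return tang / np.linalg.norm(tang, axis=-1, keepdims=True)


def _arc_length_table(width: float, depth: float, samples: int = 4097):
    t = np.linspace(0.0, 1.0, samples)
    pts = arch_point(t, width, depth)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return t, s


def tooth_slot_parameters(width: float, depth: float) -> np.ndarray:
    """Arch parameters t for the 16 tooth centers, ordered L8..L1, R1..R8.

    Right-quadrant slots are spaced by cumulative crown width along the arch
    arc from the midline; the left quadrant is the exact mirror (t -> -t).
    """
    t_tab, s_tab = _arc_length_table(width, depth)
    half_len = s_tab[-1]
    widths = CROWN_WIDTHS_MM
    # center of tooth k (type k+1) at cumulative distance from midline
    centers = np.cumsum(widths + INTER_TOOTH_GAP_MM) - 0.5 * (widths + INTER_TOOTH_GAP_MM)
    needed = centers[-1] + 0.5 * widths[-1]
    scale = half_len / needed  # stretch/squeeze slots to fill the half arch
    t_right = np.interp(centers * scale, s_tab, t_tab)
    t_left = -t_right[::-1]  # L8..L1
    return np.concatenate([t_left, t_right])
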