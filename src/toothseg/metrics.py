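"""Evaluation metrics on 3D face labelings.

Two complementary metrics: area-weighted IoU (W-IoU), where each face
contributes by its surface area so tessellation density does not bias the
overlap score, and the 95th-percentile Hausdorff distance (dH95) between the
label-boundary vertex sets of ground truth and prediction, in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import (
    FaceLabeling,
    ToothClass,
    TriangleMesh,
    face_areas,
    label_boundary_vertices,
)


class UndefinedMetricError(ValueError):
    pass


def weighted_iou(
    mesh: TriangleMesh, gt: FaceLabeling, pred: FaceLabeling, cls: ToothClass
) -> float:
    """Area-weighted IoU of one class: sum of face areas labeled ``cls`` in
    both labelings over the sum labeled ``cls`` in either.  1.0 when the
    class is absent from both, 0.0 when absent from exactly one."""
    if len(gt) != mesh.n_faces or len(pred) != mesh.n_faces:
        raise ValueError("labelings must match the mesh")
    a = gt.indices == cls.index
    b = pred.indices == cls.index
    if not a.any() and not b.any():
        return 1.0
    if not a.any() or not b.any():
        return 0.0
    areas = face_areas(mesh)
    return float(areas[a & b].sum() / areas[a | b].sum())


def hausdorff(set_a: np.ndarray, set_b: np.ndarray) -> float:
    """Symmetric Hausdorff distance: max over both directed max-min distances."""
    da, db = _directed_nn_distances(set_a, set_b)
    return float(max(da.max(), db.max()))


def hausdorff_95(set_a: np.ndarray, set_b: np.ndarray, pooled: bool = False) -> float:
    """95th-percentile Hausdorff distance (linear-interpolation percentile).

    Default is the max of the two directed 95th percentiles; ``pooled=True``
    takes the 95th percentile over the pooled nearest-neighbor distances.
    """
    da, db = _directed_nn_distances(set_a, set_b)
    if pooled:
        return float(np.percentile(np.concatenate([da, db]), 95))
    return float(max(np.percentile(da, 95), np.percentile(db, 95)))


def _directed_nn_distances(set_a: np.ndarray, set_b: np.ndarray):
    set_a = np.atleast_2d(np.asarray(set_a, dtype=np.float64))
    set_b = np.atleast_2d(np.asarray(set_b, dtype=np.float64))
    if len(set_a) == 0 or len(set_b) == 0:
        raise UndefinedMetricError("Hausdorff distance of an empty point set")
    da, _ = cKDTree(set_b).query(set_a)
    db, _ = cKDTree(set_a).query(set_b)
    return np.atleast_1d(da), np.atleast_1d(db)


@dataclass
class ToothScore:
    cls: ToothClass
    w_iou: float
    dh95: float | None  # None when the tooth is absent from the prediction


@dataclass
class CaseReport:
    per_tooth: list[ToothScore]

    @property
    def mean_w_iou(self) -> float:
        return float(np.mean([s.w_iou for s in self.per_tooth]))

    @property
    def mean_dh95(self) -> float:
        vals = [s.dh95 for s in self.per_tooth if s.dh95 is not None]
        if not vals:
            raise UndefinedMetricError("no tooth has a defined dH95")
        return float(np.mean(vals))

    def to_dict(self) -> dict:
        return {
            "per_tooth": {
                s.cls.code: {"w_iou": s.w_iou, "dh95": s.dh95} for s in self.per_tooth
            },
            "mean_w_iou": self.mean_w_iou,
            "mean_dh95": self.mean_dh95 if any(s.dh95 is not None for s in self.per_tooth) else None,
        }


def evaluate_case(
    mesh: TriangleMesh, gt: FaceLabeling, pred: FaceLabeling
) -> CaseReport:
    """Per-tooth and case-mean W-IoU / dH95 over teeth present in ground truth.

    A tooth absent from the prediction scores W-IoU 0 and its dH95 is omitted
    (``None``).  Case means are unweighted over ground-truth-present teeth.
    """
    scores = []
    for cls in gt.present_teeth():
        iou = weighted_iou(mesh, gt, pred, cls)
        if (pred.indices == cls.index).any():
            bnd_gt = label_boundary_vertices(mesh, gt, cls)
            bnd_pred = label_boundary_vertices(mesh, pred, cls)
            if len(bnd_gt) and len(bnd_pred):
                dh = hausdorff_95(bnd_gt, bnd_pred)
            else:
                dh = None
        else:
            dh = None
        scores.append(ToothScore(cls, iou, dh))
    return CaseReport(scores)
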