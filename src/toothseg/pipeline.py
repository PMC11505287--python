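"""End-to-end segmentation pipeline and the tessellation-robustness harness.

``segment_case`` runs the full chain on one arch: occlusion alignment to the
canonical landmark template, then per detected tooth a spiral view sequence,
rendering, the recurrent 2D network, binarization and unprojection; finally
multi-view-certainty region voting and connected-component cleanup merge the
per-tooth results into one face labeling.  Teeth with sentinel landmarks are
skipped.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from .align import LandmarkSet, canonical_reference, fit_rigid_alignment, apply_transform
from .mesh import FaceLabeling, ToothClass, TriangleMesh
from .nn.model import SegmentationModel, binarize, tooth_type_signal
from .synthetic import SyntheticCase, perturb_er, perturb_pfo, perturb_rvd, transfer_labels
from .metrics import evaluate_case
from .views import render_sequence, sample_views, sequence_input_array
from .voting import (
    CertaintyTable,
    build_certainty,
    cca_cleanup,
    region_voting,
    unproject_masks,
    visibility_counts,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    n_views: int = 49
    resolution: int = 256
    camera_radius: float = 15.0
    max_zenith: float = np.deg2rad(60.0)
    half_extent: float = 10.0
    depth_range: float = 40.0
    threshold: float = 0.5
    align: bool = True
    run_cca: bool = True


def segment_case(
    mesh: TriangleMesh,
    landmarks: LandmarkSet,
    model: SegmentationModel,
    cfg: PipelineConfig | None = None,
) -> tuple[FaceLabeling, CertaintyTable, dict]:
    """Segment one arch; returns (labeling, certainty table, stage report)."""
    cfg = cfg or PipelineConfig()
    report: dict = {"stages": {}}
    t0 = time.perf_counter()
    if cfg.align:
        xf = fit_rigid_alignment(landmarks, canonical_reference())
        mesh = apply_transform(mesh, xf)
        landmarks = landmarks.transformed(xf)
        report["alignment"] = xf.matrix().tolist()
    report["stages"]["align"] = time.perf_counter() - t0

    hits: dict[int, np.ndarray] = {}
    vis: dict[int, np.ndarray] = {}
    t0 = time.perf_counter()
    for slot in np.flatnonzero(landmarks.present):
        slot = int(slot)
        poses = sample_views(
            landmarks.tooth_pair(slot),
            n=cfg.n_views,
            radius=cfg.camera_radius,
            max_zenith=cfg.max_zenith,
            half_extent=cfg.half_extent,
            depth_range=cfg.depth_range,
        )
        seq = render_sequence(mesh, poses, cfg.resolution)
        x = sequence_input_array(seq, tooth_type_signal(ToothClass(slot)))
        probs, _ = model.forward(x[None], train=False)
        masks = binarize(probs[0], cfg.threshold)
        _, h = unproject_masks(masks, seq.records, mesh.n_faces)
        hits[slot] = h
        vis[slot] = visibility_counts(seq.records, mesh.n_faces)
    report["stages"]["per_tooth"] = time.perf_counter() - t0
    report["teeth_processed"] = sorted(hits)

    t0 = time.perf_counter()
    table = build_certainty(hits, vis, mesh.n_faces)
    labeling = region_voting(table)
    if cfg.run_cca:
        labeling = cca_cleanup(mesh, labeling, table)
    report["stages"]["vote_cca"] = time.perf_counter() - t0
    for stage, dt in report["stages"].items():
        log.info("[%s] %.2fs", stage, dt)
    return labeling, table, report


# ---------------------------------------------------------------------------
# Robustness harness

PERTURBATIONS = ("RVD", "PFO", "ER")


def apply_perturbation(
    mesh: TriangleMesh, kind: str, seed: int = 0, rvd_max_disp: float = 0.2,
    er_target_edge: float | None = None,
) -> TriangleMesh:
    kind = kind.upper()
    if kind == "RVD":
        return perturb_rvd(mesh, max_disp=rvd_max_disp, seed=seed)
    if kind == "PFO":
        return perturb_pfo(mesh)
    if kind == "ER":
        if er_target_edge is None:
            from .mesh import face_areas

            # median edge length as the remeshing target keeps density similar
            tri = mesh.triangles()
            e = np.linalg.norm(
                np.concatenate(
                    [tri[:, 0] - tri[:, 1], tri[:, 1] - tri[:, 2], tri[:, 2] - tri[:, 0]]
                ),
                axis=1,
            )
            er_target_edge = float(np.median(e))
        return perturb_er(mesh, er_target_edge, seed=seed)
    raise ValueError(f"unknown perturbation: {kind}")


@dataclass
class RobustnessRow:
    case_id: int
    perturbation: str
    w_iou_reference: float
    w_iou_perturbed: float

    @property
    def delta(self) -> float:
        return self.w_iou_perturbed - self.w_iou_reference


def robustness_evaluation(
    cases: list[SyntheticCase],
    model: SegmentationModel,
    perturbations: tuple[str, ...] = PERTURBATIONS,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
) -> list[RobustnessRow]:
    """Segment each case before and after each tessellation perturbation.

    Ground-truth labels are transported to the perturbed tessellation by
    nearest-face transfer; landmarks are reused (perturbations move the
    surface by well under the landmark-placement tolerance).
    """
    cfg = cfg or PipelineConfig()
    rows: list[RobustnessRow] = []
    for ci, case in enumerate(cases):
        pred_ref, _, _ = segment_case(case.mesh, case.landmarks, model, cfg)
        ref_iou = evaluate_case(case.mesh, case.labeling, pred_ref).mean_w_iou
        for kind in perturbations:
            pmesh = apply_perturbation(case.mesh, kind, seed=seed + ci)
            gt_p = transfer_labels(case.mesh, case.labeling, pmesh)
            pred_p, _, _ = segment_case(pmesh, case.landmarks, model, cfg)
            iou_p = evaluate_case(pmesh, gt_p, pred_p).mean_w_iou
            rows.append(RobustnessRow(ci, kind, ref_iou, iou_p))
    return rows


def summarize_robustness(rows: list[RobustnessRow]) -> dict[str, dict]:
    out: dict[str, dict] = {}
    for kind in sorted({r.perturbation for r in rows}):
        sel = [r for r in rows if r.perturbation == kind]
        deltas = np.array([r.delta for r in sel])
        out[kind] = {
            "mean_delta_w_iou": float(deltas.mean()),
            "mean_abs_delta_w_iou": float(np.abs(deltas).mean()),
            "n_cases": len(sel),
        }
    return out
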