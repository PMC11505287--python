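"""Losses, mesh-level augmentation, 2D target generation and the training loop.

Training renders each (case, tooth) pair on the fly: meshes are augmented by
random rigid+scale transforms (applied to vertices and landmarks alike, after
occlusion alignment), views are sampled along the spiral trajectory and
rendered, and binary targets are read off the first-hit tables.  No 2D
augmentation is applied to the rendered maps.  Optimization is AdamW with
cosine annealing warm restarts, minimizing a deep-supervised Dice loss.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import LandmarkSet, RigidTransform
from .mesh import FaceLabeling, ToothClass, TriangleMesh
from .nn.model import AdamW, NetworkConfig, SegmentationModel
from .synthetic import SyntheticCase
from .views import RenderRecord, ViewSequence, render_sequence, sample_views, sequence_input_array
from .nn.model import tooth_type_signal

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Losses


def dice_loss(pred: np.ndarray, ref: np.ndarray, eps: float = 1.0) -> float:
    """Soft Dice loss 1 - (2 sum(p r) + eps) / (sum(p) + sum(r) + eps)."""
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    num = 2.0 * (pred * ref).sum() + eps
    den = pred.sum() + ref.sum() + eps
    return float(1.0 - num / den)


def dice_loss_grad(pred: np.ndarray, ref: np.ndarray, eps: float = 1.0) -> np.ndarray:
    """Analytic gradient of ``dice_loss`` with respect to ``pred``."""
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    num = 2.0 * (pred * ref).sum() + eps
    den = pred.sum() + ref.sum() + eps
    return (num - 2.0 * ref * den) / (den * den)


def _downsample_nn(ref: np.ndarray, h: int, w: int) -> np.ndarray:
    """Nearest-neighbor downsampling of a (..., H, W) binary reference."""
    big_h, big_w = ref.shape[-2], ref.shape[-1]
    rows = (np.arange(h) * big_h) // h
    cols = (np.arange(w) * big_w) // w
    return ref[..., rows[:, None], cols[None, :]]


def deep_supervised_loss(
    stage_preds: list[np.ndarray], ref: np.ndarray, eps: float = 1.0
) -> float:
    """Unweighted sum of Dice losses over all heads; the reference is
    downsampled (nearest neighbor) to each auxiliary head's resolution.
    The last entry of ``stage_preds`` is the full-resolution final head."""
    if not stage_preds:
        raise ValueError("need at least one head")
    total = 0.0
    for pred in stage_preds:
        r = _downsample_nn(ref, pred.shape[-2], pred.shape[-1])
        total += dice_loss(pred, r, eps)
    return total


# ---------------------------------------------------------------------------
# Augmentation


@dataclass
class AugmentTransform:
    """Rigid + isotropic-scale augmentation: v' = s (R v) + t."""

    rotation: np.ndarray  # 3x3
    translation: np.ndarray  # mm
    scale: float
    angle: float
    axis: np.ndarray

    @classmethod
    def sample(cls, rng: np.random.Generator) -> "AugmentTransform":
        angle = rng.uniform(-np.pi / 4, np.pi / 4)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        k = np.array(
            [
                [0, -axis[2], axis[1]],
                [axis[2], 0, -axis[0]],
                [-axis[1], axis[0], 0],
            ]
        )
        rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
        return cls(
            rotation=rot,
            translation=rng.uniform(-5.0, 5.0, size=3),
            scale=float(rng.uniform(0.8, 1.2)),
            angle=float(angle),
            axis=axis,
        )

    @classmethod
    def identity(cls) -> "AugmentTransform":
        return cls(np.eye(3), np.zeros(3), 1.0, 0.0, np.array([0.0, 0.0, 1.0]))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        return self.scale * (pts @ self.rotation.T) + self.translation


def augment_mesh(mesh: TriangleMesh, xf: AugmentTransform) -> TriangleMesh:
    return TriangleMesh(xf.apply_points(mesh.vertices), mesh.faces.copy())


def augment_case(case: SyntheticCase, xf: AugmentTransform) -> SyntheticCase:
    """Transform mesh and landmarks identically; labels are untouched."""
    rigid = RigidTransform(xf.rotation, xf.translation)
    landmarks = case.landmarks.transformed(rigid, scale=xf.scale)
    return SyntheticCase(augment_mesh(case.mesh, xf), case.labeling, landmarks)


# ---------------------------------------------------------------------------
# Targets


def make_targets(
    labeling: FaceLabeling, tooth: ToothClass, records: list[RenderRecord]
) -> np.ndarray:
    """(n, H, W) binary targets: 1 iff the pixel's first-hit face is labeled
    ``tooth``; background pixels are 0."""
    if not (labeling.indices == tooth.index).any():
        raise ValueError(f"tooth {tooth.code} absent from labeling")
    lbl = np.concatenate([labeling.indices, [-1]])  # sentinel -1 row
    out = np.empty((len(records),) + records[0].first_hit.shape, dtype=np.float32)
    for i, rec in enumerate(records):
        out[i] = lbl[rec.first_hit] == tooth.index
    return out


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainConfig:
    batch_size: int = 4
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    restart_period: int = 10_000
    seq_len: int = 49
    eps: float = 1.0
    val_fraction: float = 0.2  # 4:1 train/validation split
    n_augment: int = 10
    resample_augment: bool = False
    iterations: int = 2000
    val_every: int = 50
    val_sequences: int = 8
    resolution: int = 256
    camera_radius: float = 15.0
    half_extent: float = 10.0
    depth_range: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.seq_len, self.iterations) < 1:
            raise ValueError("config values must be positive")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0,1)")


@dataclass
class TrainResult:
    model: SegmentationModel
    history: list[dict]
    best_val_loss: float
    train_indices: list[int]
    val_indices: list[int]


def _render_pair(
    case: SyntheticCase,
    slot: int,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
) -> tuple[np.ndarray, np.ndarray]:
    poses = sample_views(
        case.landmarks.tooth_pair(slot),
        n=train_cfg.seq_len,
        radius=train_cfg.camera_radius,
        half_extent=train_cfg.half_extent,
        depth_range=train_cfg.depth_range,
    )
    seq = render_sequence(case.mesh, poses, train_cfg.resolution)
    cls = ToothClass(slot)
    x = sequence_input_array(seq, tooth_type_signal(cls))
    y = make_targets(case.labeling, cls, seq.records)
    return x, y


def _batch_loss_and_grads(
    model: SegmentationModel,
    xs: np.ndarray,
    ys: np.ndarray,
    eps: float,
) -> float:
    """Deep-supervised Dice loss, per view (each output map is one Dice term),
    averaged over batch and views; accumulates parameter gradients."""
    probs, aux = model.forward(xs, train=True)
    bsz, n_views = xs.shape[0], xs.shape[1]
    scale = 1.0 / (bsz * n_views)
    total = 0.0
    dprobs = np.zeros_like(probs)
    daux = [np.zeros_like(a) for a in aux]
    for b in range(bsz):
        for v in range(n_views):
            total += dice_loss(probs[b, v], ys[b, v], eps)
            dprobs[b, v] = dice_loss_grad(probs[b, v], ys[b, v], eps) * scale
            for i, a in enumerate(aux):
                r = _downsample_nn(ys[b, v], a.shape[-2], a.shape[-1])
                total += dice_loss(a[b, v], r, eps)
                daux[i][b, v] = dice_loss_grad(a[b, v], r, eps) * scale
    model.backward(dprobs, daux if aux else None)
    return total * scale


def train(
    cases: list[SyntheticCase],
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    checkpoint_path: str | Path | None = None,
) -> TrainResult:
    """Train the segmentation network on labeled cases.

    Cases are split 4:1 into train/validation; each training mesh
    contributes its aligned original plus ``n_augment`` fixed random
    rigid+scale variants (sampled once per run unless ``resample_augment``).  Each iteration draws ``batch_size``
    (case, augmentation, tooth) sequences, renders them and takes one AdamW
    step on the deep-supervised Dice loss.  The best-validation-loss weights
    are restored (and saved) at the end.
    """
    if len(cases) < 2:
        raise ValueError("need at least 2 cases to split train/validation")
    rng = np.random.default_rng(train_cfg.seed)
    order = rng.permutation(len(cases))
    n_val = max(1, round(train_cfg.val_fraction * len(cases)))
    val_idx = sorted(int(i) for i in order[:n_val])
    train_idx = sorted(int(i) for i in order[n_val:])

    def make_augments():
        # the aligned original is kept as variant 0 alongside the random
        # rigid+scale copies
        return [
            [AugmentTransform.identity()]
            + [AugmentTransform.sample(rng) for _ in range(train_cfg.n_augment)]
            for _ in train_idx
        ]

    augments = make_augments()
    aug_cache: dict[tuple[int, int], SyntheticCase] = {}

    def augmented(ci_pos: int, ai: int) -> SyntheticCase:
        key = (ci_pos, ai)
        if key not in aug_cache:
            aug_cache[key] = augment_case(cases[train_idx[ci_pos]], augments[ci_pos][ai])
        return aug_cache[key]

    # enumerate training sequences: (train-case position, augment idx, tooth slot)
    items: list[tuple[int, int, int]] = []
    for pos, ci in enumerate(train_idx):
        slots = [t.index for t in cases[ci].labeling.present_teeth()]
        for ai in range(train_cfg.n_augment + 1):  # 0 = aligned original
            for s in slots:
                items.append((pos, ai, s))
    val_items: list[tuple[int, int]] = []
    for ci in val_idx:
        for t in cases[ci].labeling.present_teeth():
            val_items.append((ci, t.index))

    # cache rendered sequences when the whole training set fits comfortably
    # in memory (small overfit-style runs re-draw the same sequences often)
    seq_bytes = train_cfg.seq_len * 5 * train_cfg.resolution**2 * 4
    cache_renders = len(items) * seq_bytes < 300 * 2**20
    render_cache: dict[tuple[int, int, int], tuple[np.ndarray, np.ndarray]] = {}

    def rendered(pos: int, ai: int, slot: int):
        if not cache_renders:
            return _render_pair(augmented(pos, ai), slot, net_cfg, train_cfg)
        key = (pos, ai, slot)
        if key not in render_cache:
            render_cache[key] = _render_pair(
                augmented(pos, ai), slot, net_cfg, train_cfg
            )
        return render_cache[key]

    model = SegmentationModel(net_cfg)
    opt = AdamW(
        model.params(),
        lr=train_cfg.learning_rate,
        weight_decay=train_cfg.weight_decay,
        restart_period=train_cfg.restart_period,
    )
    history: list[dict] = []
    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    best_bn: list[tuple[np.ndarray, np.ndarray]] | None = None

    for it in range(1, train_cfg.iterations + 1):
        if train_cfg.resample_augment and it % max(1, len(items) // train_cfg.batch_size) == 0:
            augments = make_augments()
            aug_cache.clear()
            render_cache.clear()
        picks = rng.choice(len(items), size=train_cfg.batch_size, replace=True)
        xs, ys = [], []
        for p in picks:
            pos, ai, slot = items[p]
            x, y = rendered(pos, ai, slot)
            xs.append(x)
            ys.append(y)
        xs = np.stack(xs)
        ys = np.stack(ys)
        opt.zero_grad()
        loss = _batch_loss_and_grads(model, xs, ys, train_cfg.eps)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss at iteration {it}: {loss}")
        opt.step()
        entry = {"iteration": it, "train_loss": float(loss), "lr": opt.current_lr()}

        if it % train_cfg.val_every == 0 or it == train_cfg.iterations:
            vloss = _validation_loss(model, cases, val_items, net_cfg, train_cfg, rng)
            entry["val_loss"] = vloss
            if vloss < best_val:
                best_val = vloss
                best_state = [p.value.copy() for p in model.params()]
                best_bn = [
                    (bn.running_mean.copy(), bn.running_var.copy())
                    for bn in model.bn_layers()
                ]
            log.info("iter %d train %.4f val %.4f", it, loss, vloss)
        history.append(entry)

    if best_state is not None:
        for p, v in zip(model.params(), best_state):
            p.value = v
        for bn, (rm, rv) in zip(model.bn_layers(), best_bn):
            bn.running_mean, bn.running_var = rm, rv
    if checkpoint_path is not None:
        model.save(checkpoint_path)
        Path(str(checkpoint_path) + ".log.json").write_text(json.dumps(history))
    return TrainResult(model, history, float(best_val), train_idx, val_idx)


def _validation_loss(model, cases, val_items, net_cfg, train_cfg, rng) -> float:
    picks = rng.choice(
        len(val_items), size=min(train_cfg.val_sequences, len(val_items)), replace=False
    )
    losses = []
    for p in picks:
        ci, slot = val_items[p]
        x, y = _render_pair(cases[ci], slot, net_cfg, train_cfg)
        probs, _ = model.forward(x[None], train=False)
        losses.extend(
            dice_loss(probs[0, v], y[v], train_cfg.eps) for v in range(len(y))
        )
    return float(np.mean(losses))
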