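"""Train a reduced network on synthetic arches and segment a held-out case.

Desk-scale demonstration of the full learning pipeline: a small U-Net +
bi-directional ConvLSTM (widths [8,16,32], 8 recurrent channels) is trained
on 9-view sequences at 96x96 from a handful of synthetic jaws, then the full
segment pipeline (align -> render -> predict -> unproject -> vote -> CCA)
runs on a case the network never saw.  Expect a few minutes on one CPU;
raise `iterations` for better quality.
"""

from toothseg import (
    NetworkConfig,
    PipelineConfig,
    TrainConfig,
    evaluate_case,
    generate_jaw,
    sample_spec,
    segment_case,
    train,
)

cases = [generate_jaw(sample_spec(seed)) for seed in range(6)]
held_out = generate_jaw(sample_spec(99))

net_cfg = NetworkConfig(
    stage_widths=[8, 16, 32], recurrent_hidden=8, resolution=96, seed=0
)
train_cfg = TrainConfig(
    seq_len=9, resolution=96, iterations=120, val_every=30,
    n_augment=2, learning_rate=5e-3, restart_period=120, seed=0,
)
result = train(cases, net_cfg, train_cfg)
print(f"best validation Dice loss: {result.best_val_loss:.3f}")

pipe = PipelineConfig(n_views=9, resolution=96)
pred, table, report = segment_case(held_out.mesh, held_out.landmarks, result.model, pipe)
scores = evaluate_case(held_out.mesh, held_out.labeling, pred)
print(f"held-out case mean W-IoU: {scores.mean_w_iou:.3f}")
print("per-tooth:", {s.cls.code: round(s.w_iou, 2) for s in scores.per_tooth})
print("(short demo training; the acceptance-scale run trains longer on 20 jaws)")
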