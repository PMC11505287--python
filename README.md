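# toothseg

Projection-based per-tooth segmentation of 3D dental surface scans.

Orthodontic treatment planning needs every face of an intra-oral scan — a
triangle mesh of one dental arch — labeled as one of sixteen teeth
(`L8..L1`, `R1..R8`: third molar to central incisor per quadrant) or gingiva
`G`.  Real orthodontic cases are hard: crowding, missing and damaged teeth,
retention, appliances.  `toothseg` implements a detect-and-segment,
multi-view approach for this task, together with a synthetic jaw generator
so the whole pipeline can be trained, evaluated and stress-tested at desk
scale on one CPU.

## The method

Given per-tooth mesial/distal surface landmarks (an input; missing teeth
carry an infinity sentinel):

1. **Occlusion alignment** — closed-form orthogonal Procrustes (Kabsch) fit
   of the landmarks to a canonical arch template puts the scan upright along
   z and centered at the origin.
2. **Next-view sampling** — for each tooth, 49 orthographic cameras on a
   15 mm sphere around the landmark midpoint follow a golden-angle spiral
   from the occlusal pole, always looking at the tooth.
3. **Rendering** — each view yields a depth map (`0` = background, nearer =
   larger), a screen-space normal map, and a pixel → first-hit-face table
   (z-buffer rasterization ≡ per-pixel orthographic ray casting).
4. **Recurrent 2D segmentation** — a shared-weight U-Net conditioned on a
   tooth-type scalar `i_tt = (slot+1)/16`, followed by a bi-directional
   convolutional LSTM across the view sequence, predicts binary per-view
   masks (task: "segment *the* tooth at the center").  Training minimizes a
   deep-supervised soft Dice loss
   `L = 1 − (2Σpᵢrᵢ + ε)/(Σpᵢ + Σrᵢ + ε)` with AdamW and cosine annealing.
5. **Unprojection and region voting** — mask pixels are cast back through
   the first-hit table.  The *multi-view certainty* of face `f` for class
   `c` is `u(f,c) = #views hitting f / #views seeing f`; every face takes
   `argmax_c u(f,c)`, or gingiva when all certainties vanish — so no face
   ever carries two classes.
6. **Connected-component cleanup** — per class only the largest
   edge-connected component survives; stray faces fall to their next-best
   class (if adjacent to its region) or gingiva, so each tooth is a single
   region.

Evaluation uses area-weighted IoU, `W-IoU = Σ_{f∈F∩} A_f / Σ_{f∈F∪} A_f`,
and the 95th-percentile symmetric Hausdorff distance `dH95` between
label-boundary vertex sets (mm).

The network is implemented in numpy (float32) with hand-written
backpropagation — convolutions as im2col + BLAS matmuls, backprop-through-
time for the recurrent unit — and every layer is gradient-checked in the
test suite.  See `docs/methods.md` for models, parameters and numerical
choices.

## Worked example

`examples/04_round_trip_voting.py` renders every tooth's ground-truth masks
on a synthetic arch (49 views, 256²), unprojects them, and runs voting +
cleanup — measuring whether the 2D detour loses information:

```
$ python examples/04_round_trip_voting.py
mean W-IoU after the 2D round trip: 1.0000
per-tooth W-IoU: {'L8': 1.0, 'L7': 1.0, ..., 'R8': 1.0}
values at/near 1.0 show the projection pipeline preserves the labeling
```

A W-IoU of 1.0 per tooth means every face visible to its tooth's cameras is
recovered with the correct label: projection, unprojection and voting are
collectively lossless on this arch.  The other examples cover generation
(`01`), alignment (`02`, pose recovered to ~1e-7 against the case's own
landmarks), rendering (`03`, 100% face coverage at 49 views), desk-scale
training (`05`), and tessellation perturbations (`06`).

A thin CLI mirrors the library:

```bash
toothseg --seed 4 synth --out case.ply         # mesh + label/landmark sidecars
toothseg align case.ply case.ply.landmarks.json --out aligned.ply
toothseg train --synthetic-cases 8 --checkpoint model.npz
toothseg segment case.ply case.ply.landmarks.json \
         --checkpoint model.npz --out pred.labels.txt
toothseg evaluate case.ply case.ply.labels.txt pred.labels.txt
toothseg robustness --checkpoint model.npz --n-cases 5
```

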