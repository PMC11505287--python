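# Methods

This note documents the models, algorithms and numerical choices behind
`toothseg`, in the spirit of a methods appendix: what the pipeline computes,
which knobs matter, what the synthetic data does and does not emulate, and
where genuinely open design points were settled.

## Problem setting

A dental surface scan is a triangle mesh `M = (V, F)` of one arch (maxilla
or mandible), with no guarantees about manifoldness, closure, orientation or
resolution.  The goal is a face labeling `g : F -> C` over 17 classes: 16
individual teeth, written `L8..L1` (patient-left third molar to central
incisor) and `R1..R8`, plus gingiva `G`.  Internally classes are indexed
0..16 in that anatomical order with `G = 16`; argmax tie-breaks and the
tooth-type encoding both use this order.

The pipeline is detect-and-segment: per-tooth mesial/distal surface
landmarks are an *input* (in clinical use they come from a separate detector
and can be corrected by the clinician; here the synthetic generator provides
them).  Teeth whose landmarks carry the infinity sentinel are skipped
everywhere.

## Occlusion alignment

Landmarks are fitted to a shipped reference template by closed-form weighted
orthogonal Procrustes (Kabsch), with the standard reflection guard (if the
solution has determinant −1 the smallest singular direction is flipped).
Correspondences are known — tooth slot and mesial/distal role — so an
iterative closest-point loop would re-derive fixed correspondences and then
solve the same closed-form problem; on exact correspondences both give the
identical transform.  Degenerate (collinear) configurations and fewer than
two shared teeth raise errors.

The reference template is a symmetric full-arch layout derived from the same
parametric arch model the synthetic generator uses: tooth slots along a
parabolic arch (width 64 mm, depth 54 mm) spaced by typical mesiodistal
crown widths, landmarks offset ±0.7·a along the arch tangent (a = crown
footprint semi-axis) at the height of the crown dome at that offset.  Left
and right quadrants are exact mirrors, and the x/y landmark mean is the
origin; "canonical pose" means upright along +z, occlusal surfaces facing
+z, origin-centered.

## Per-tooth multi-view rendering

For each present tooth, cameras sit on a sphere of radius 15 mm centered on
the mean of the tooth's two landmarks.  Pose 0 looks straight down (+z);
pose i sits at zenith `max_zenith · i/(n−1)` and azimuth `i · azimuth_step`,
always looking at the center.  Defaults: n = 49 views, max_zenith = 60°,
azimuth step = golden angle (137.508°), orthographic viewport half-extent
10 mm, depth range 40 mm, 256×256 pixels.  The golden-angle spiral gives a
uniform, non-repeating azimuth coverage; 60° zenith keeps the gingival base
from occluding the crown.  All of these are configuration keys.

Each view yields a depth map (0 = background/infinity; otherwise
`1 − t/depth_range`, so nearer surfaces are brighter), a screen-space normal
map (face normals rotated into camera coordinates and flipped per pixel so
the component toward the camera is non-negative — face rather than vertex
normals because input orientation is untrusted and flat shading is
unambiguous on non-manifold input), and a pixel → first-hit-face table.

Rendering is implemented as an orthographic z-buffer rasterizer over pixel
centers (numba-compiled), which produces exactly the nearest ray-triangle
intersection per pixel-center ray; the test suite checks it bit-for-bit
against an independent Möller–Trumbore ray-casting oracle.  Pixel centers
are at `(i+0.5)/H` of the viewport; image row 0 is the top (+up).  Hits
beyond the depth range or behind the camera count as background.

## Segmentation network

The task is binary per-view segmentation of *the* tooth at the sequence
center; class identity enters only through the tooth-type scalar
`i_tt = (slot_index + 1)/16 ∈ (0, 1]` (distinct per tooth type, L8 → 1/16 …
R8 → 1).  The input per view is 5 channels: depth, 3 normal components, and
a constant `i_tt` plane.  Feeding the scalar as an input channel is the
simplest mechanism that lets one shared network specialize per tooth type; a
decoder-side additive embedding was considered and rejected as more
invasive for no demonstrated gain at this scale.

Architecture: a per-view shared-weight U-Net (default widths
[32, 64, 128, 256, 512]; 3×3 same-padding convolutions; batch normalization
between each convolution and its ReLU; 2×2 max pooling; 2×2
transposed-convolution upsampling) produces full-resolution feature maps
(width = first stage width).  A bi-directional convolutional LSTM (3×3
gates, default 32 hidden channels per direction, no peephole terms)
correlates the feature maps along the view axis; the two directions'
hidden states are concatenated and a 1×1 convolution + sigmoid yields
per-view foreground probabilities.  "Bi-directional with 32 states in both
layers" is read as the two directions of one bi-directional layer; a
2-layer stacked variant exists behind `stacked_recurrent`.  Deep
supervision attaches a 1×1 sigmoid head to every decoder stage; the total
loss is the unweighted sum of the per-head Dice losses, with the reference
mask downsampled to each head by nearest neighbor (downsampling targets is
cheaper than upsampling predictions and standard for deep supervision).

Masks are binarized at probability > 0.5 (strict).

The stack is implemented in numpy (float32) with hand-written
backpropagation: im2col convolutions via nine block-slice copies and batched
BLAS matmuls, and backprop-through-time for the recurrent unit.  Every
layer's backward pass is verified against finite differences in the test
suite.

## Training

Loss: soft Dice, `1 − (2Σpr + ε)/(Σp + Σr + ε)` with ε = 1.0 (ε is a
stability term; 1.0 makes the loss exactly 0 for an all-background image
predicted as all-background).  The Dice term is computed *per view* — each
output map is one binary segmentation image — and averaged over batch and
views; a sequence-level pooled Dice was tried and converges more slowly
because views where the tooth is small contribute almost no gradient.
Optimizer: AdamW (decoupled weight decay), learning rate and weight decay
10⁻³, cosine annealing warm restarts every 10,000 iterations.  Batches of 4
sequences.

Cases are split 4:1 into train/validation.  Each training mesh contributes
its aligned original plus 10 random rigid+scale augmentations (rotation up
to ±45° about a uniform random axis, translation per coordinate uniform in
±5 mm, isotropic scale uniform in [0.8, 1.2]), applied to vertices and
landmarks alike *after* occlusion alignment; rendering happens per
augmented mesh and no 2D augmentation is applied to the maps.
Augmentations are sampled once per run (a `resample_augment` flag re-draws
them periodically).  Binary targets come from the first-hit table: pixel =
1 iff its first-hit face carries the tooth's ground-truth label.

Because an orthographic camera rig is anchored to the (co-transformed)
landmarks, a rigid+scale augmentation changes the rendered maps only through
apparent scale and the in-plane orientation convention of the up vector —
exactly the invariances the augmentation is meant to teach.

The training loop renders batches on the fly (a 9-view 96² batch renders in
~0.2 s) and keeps the best-validation-loss weights.  Checkpoints are npz
archives with the configuration embedded.

### Desk-scale configuration

The package is exercised end-to-end at a reduced scale chosen to fit a
single CPU: widths [8, 16, 32] with 8 recurrent channels, 9 views at 96²,
20 synthetic jaws (16 train / 4 validation).  At this scale a learning rate
of 5×10⁻³ with a single cosine annealing cycle (restart period = total
iterations, so the rate decays to ~0 by the end) converges substantially
faster than the full-scale defaults; batch size stays 4.  Training lengths
for the bundled tests were set from loss-convergence curves on synthetic
data (a few hundred iterations), and the problem sizes above are the
package's chosen study conditions for self-verification, not
recommendations for real scans.

The dominant residual error at desk scale is a one-to-two-face ring of
gingiva claimed around each crown: a single stray mask pixel in any view
gives a face nonzero certainty, and gingiva wins only at exactly zero, so
per-view boundary jitter converts into claimed gingiva area through a union
over views.  At 96² (0.21 mm/pixel) the reduced network's 2D masks keep a
roughly ±1-pixel boundary jitter however long they train (per-view Dice
plateaus near 0.95), which places a hard ceiling on the 3D overlap score
that scales with the *face size* of the mesh: on 1 mm-edge meshes the
overfit W-IoU ceiling is ≈0.82, on the default 0.5 mm meshes ≈0.92.  On
clinical-density scans (~0.2 mm edges) the identical pixel jitter would
cost only ~2%.  This quantization coupling between image resolution and
tessellation density is the main thing to know when running the pipeline
at reduced scale.  The bundled self-tests train ~160-240 iterations (about
10 minutes each on one CPU); single-jaw overfit runs reach W-IoU ≈ 0.91 ±
0.03 under these conditions.

## Unprojection, certainty, voting, cleanup

Unprojection reads the first-hit table at mask-positive pixels; only the
first (nearest) intersection along each pixel ray contributes, so occluded
faces are never labeled through the surface.  Hit counting is per view — a
face hit by fifty pixels of one view counts once — because the certainty
denominator is also a view count.

Multi-view certainty of (face, class) = hits / visibility, where visibility
counts the views *of that class's own camera rig* in which the face was
first-hit visible; faces never visible get certainty 0.  Region voting
assigns each face its argmax-certainty class (ties break toward the lower
class index, i.e. anatomically from L8; gingiva when all certainties are 0).
This resolves multi-class claims in one deterministic pass.

Connected-component cleanup enforces one region per tooth: per class,
edge-connected components are found and only the largest survives (ties:
larger total area, then lowest contained face index — the face-count rule is
primary).  Faces of discarded components go to their highest-certainty class
whose retained region is edge-adjacent (single pass, in face-index order, so
a chain of discarded faces can re-attach consecutively — including to their
own class when adjacency permits), else gingiva.

## Metrics

* **W-IoU** — area-weighted IoU per class: Σ areas of faces labeled c in
  both over Σ in either.  Area weighting makes the score invariant to
  refining a face into same-labeled children; with ~200k-face clinical
  meshes and strongly varying triangle sizes an unweighted IoU would be
  biased by tessellation density.  Conventions: 1 if the class is empty in
  both labelings, 0 if empty in exactly one.
* **dH95** — both labelings' boundary vertex sets (vertices incident to at
  least one face of the class and one face of another class) are compared by
  the 95th percentile (linear interpolation) of nearest-neighbor distances,
  symmetrized as the max over the two directions.  A pooled-percentile
  variant is available (`pooled=True`); the symmetric-max reading is the
  default because it cannot hide a one-sided artifact.  Empty boundary sets
  make the metric undefined (error), and a tooth absent from the prediction
  reports W-IoU 0 with dH95 omitted.
* Case aggregation is the unweighted mean over teeth present in ground
  truth; per-tooth values are always reported alongside.

## Synthetic jaw generator

The generator emulates a single dental arch at desk scale:

* **Arch**: parabola in the occlusal plane (width 64 mm, depth 54 mm by
  default — sized so the 16 standard crown widths fit the arc at ~0.6 mm
  spacing), teeth placed by arc length, exact left/right mirror symmetry.
* **Crowns**: convex ovoid domes — superellipse footprint (exponent 3) with
  paraboloid height profile; mesiodistal semi-axis `0.5·width − 0.25 mm`,
  bucco-lingual `0.48·width`, heights 4–5.5 mm by tooth type.  The
  paraboloid apex radius (a²/2h, a few mm) keeps the occlusal surface
  resolvable at the default 1 mm tessellation.
* **Gingiva**: a band sheet (half-width 6.5 mm) around the arch with a mild
  sinusoidal corrugation (0.25 mm default).
* **Compositing**: height-field z-max of base and crown fields on a regular
  grid (cell ≈ 0.85 × target edge), triangulated per cell.  Height-field
  compositing guarantees each crown's "winning" region is connected without
  exact-arithmetic booleans.  Faces are labeled by the argmax crown
  contribution at their centroid when it exceeds 0.25 mm, else gingiva;
  sub-5% slivers where two crowns meet are absorbed into gingiva, and any
  larger fragmentation or a fully swallowed tooth raises a generation error
  naming the teeth.
* **Anomalies**: per-tooth presence flags (missing teeth), positional jitter
  (crowding; displacement uniform in a disk), rotation about the local
  vertical, crown scale, and eruption offset (retention).  `sample_spec`
  draws study-condition cases: 0–3 missing teeth, jitter up to 0.5 mm,
  rotations up to ±0.25 rad, ±8% crown scale, occasional 0.5–1.5 mm
  retention.
* **Landmarks**: mesial/distal at ±0.7·a along the arch tangent from the
  crown center (mesial toward the midline), evaluated on the analytic
  surface and snapped to the mesh by closest-point projection.
* Generation is deterministic given the ``JawSpec`` (including its seed), and the
  scene is born in canonical pose.

What it does *not* emulate: scanner noise and holes, fissured occlusal
anatomy, interproximal contact geometry of real crowding, roots/appliances,
color/texture, or maxilla/mandible shape differences (the pipeline treats
both identically after alignment).  Tests passing on this generator
demonstrate the pipeline's correctness and internal consistency — not
clinical accuracy on real scans.

## Tessellation perturbations

* **RVD** — every vertex moves along a uniform random direction by a
  magnitude uniform in [0, 0.2] mm (the 0.2 mm cap mirrors typical
  intra-oral scanner error); topology untouched.
* **PFO** — interior manifold edges are flipped when the flip raises the
  minimum interior angle of the two incident triangles, restricted to nearly
  coplanar pairs (dihedral < 15°) so the discretized geometry is preserved;
  vertex positions untouched; iterated to a fixed point (≤10 passes).
* **ER** — isotropic remeshing: split edges > 4/3·target, collapse edges
  < 4/5·target (midpoint, with link-condition and overlong-edge guards),
  flip toward valence 6, tangentially relax with projection back onto the
  input surface; 4 iterations.  Vertices on sharp edges (dihedral > 35°,
  e.g. the gingival margin) are frozen so creases are not cut across.  The
  4/3, 4/5, 0.1 mm-fidelity and 35° constants are this package's choices —
  the standard isotropic-remeshing schedule — not values from any external
  tool.

Ground-truth labels travel to a perturbed tessellation by nearest-source-
face transport (centroid k-d tree + exact point-triangle distance).

## Numerical and degenerate-input choices

* Degenerate faces (repeated vertices or zero area) are dropped at load with
  a logged count, never repaired; downstream rendering tolerates holes.
* Mesh edges are derived from faces on demand and never stored.
* Label sidecars are newline-delimited class codes in face storage order
  (diff-able, dependency-free); a JSON first-line header variant is accepted
  on read.  Landmark sidecars are JSON with `null` for missing teeth.
* The certainty table stores integer hit/visible counts, so certainties are
  exact rationals and voting ties are reproducible.
* Z-buffer ties (two triangles at the identical depth at a pixel center)
  keep the first triangle in face order — deterministic.
* Float32 throughout the network; Dice and its gradient are computed in
  float64.  BLAS thread count does not affect test tolerances.

## Known limitations

* Very narrow interdental gaps can be invisible to every camera of both
  adjacent teeth; such faces keep certainty 0 and fall to gingiva — the
  known failure mode of projection methods in tight contacts.
* The CPU implementation is for desk-scale verification: full-scale (49
  views, 256², widths to 512) training is out of reach without GPU compute;
  inference at full scale runs but slowly (~minutes per arch).
* The reference landmark template is generic; alignment quality on real
  scans depends on how well the patient's arch matches a parabolic layout
  (the Procrustes fit absorbs global pose, not arch-shape variation).
* `perturb_pfo`'s coplanarity guard means it leaves strongly curved regions
  untouched rather than degrading them — intentional, but it makes PFO the
  mildest perturbation by construction.
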