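"""Occlusion alignment: recover an unknown rigid pose from landmarks.

Applies a random rotation + translation to a synthetic arch, then recovers
the canonical pose by fitting its landmarks to the shipped reference
template (closed-form Kabsch on known tooth-slot correspondences).
"""

import numpy as np

from toothseg import (
    JawSpec,
    apply_transform,
    canonical_reference,
    fit_rigid_alignment,
    generate_jaw,
)
from toothseg.align import RigidTransform

case = generate_jaw(JawSpec(seed=1))

# simulate a scanner pose: rotate 30 degrees about a skew axis, translate
angle = np.deg2rad(30)
axis = np.array([1.0, 2.0, 0.5])
axis /= np.linalg.norm(axis)
k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
pose = RigidTransform(rot, np.array([12.0, -4.0, 7.0]))

moved_mesh = apply_transform(case.mesh, pose)
moved_landmarks = case.landmarks.transformed(pose)

recovered = fit_rigid_alignment(moved_landmarks, canonical_reference())
aligned = apply_transform(moved_mesh, recovered)

residual = recovered.compose(pose)
rot_err = np.linalg.norm(residual.rotation - np.eye(3))
print(f"rotation residual (Frobenius): {rot_err:.2e}")
print(f"translation residual: {np.linalg.norm(residual.translation):.2e} mm")
print("(the applied pose is undone up to the small, sub-0.1-mm-scale mismatch")
print(" between this particular arch and the generic reference template;")
print(" fitting against the arch's own landmarks recovers the pose to ~1e-7)")
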