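"""Rigid inter-time-point alignment and blood-VOI propagation.

Moves the phantom by a known rigid transform (as a patient repositioned
between acquisitions), registers the CT channels, and propagates the
60-min blood-pool VOI to the moved frame.
"""

import numpy as np

from fapitbr import PhantomConfig, RigidTransform, generate_phantom, register_rigid
from fapitbr.timepoints import apply_transform, propagate_voi
from fapitbr.voi import make_sphere_voi

result = generate_phantom(PhantomConfig(noise_sd_frac=0.0, seed=3))
ct = result.ct_ref

true = RigidTransform.from_euler(angles_deg=(0.0, 2.0, -3.0), translation_mm=(6.0, -4.0, 2.0))
moved_ct = apply_transform(ct, true.inverse(), ct)

estimated = register_rigid(ct, moved_ct)
t_err = np.abs(estimated.translation_mm - true.translation_mm).max()
a_err = abs(estimated.rotation_angle_deg - true.rotation_angle_deg)
print(f"true translation   {np.round(true.translation_mm, 2)} mm")
print(f"estimated          {np.round(estimated.translation_mm, 2)} mm  (max error {t_err:.3f} mm)")
print(f"rotation angle     true {true.rotation_angle_deg:.2f} deg, estimated "
      f"{estimated.rotation_angle_deg:.2f} deg (error {a_err:.3f} deg)")

voi = make_sphere_voi((0.0, 0.0, 0.0), 10.0, ct)
propagated = propagate_voi(voi, estimated, moved_ct)
target = true.apply_points([[0.0, 0.0, 0.0]])[0]
err = np.linalg.norm(propagated.centroid_mm() - target)
print(f"propagated VOI centroid error: {err:.2f} mm (voxel size 3 mm)")
print()
print("Registration errors well under half a voxel mean blood statistics can")
print("be recomputed on each time point's native image through one transform.")
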