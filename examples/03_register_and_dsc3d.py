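"""Track B: landmark + ICP rigid registration, then 3D Dice and volumes.

Six ordered landmarks give a closed-form initial rigid transform; trimmed
point-to-point ICP on surface point clouds refines it.  The model volume is
then resampled onto the gold-standard grid and scored in 3D.
"""

import numpy as np

from cartival import (
    PhantomParams,
    RigidTransform,
    dsc_3d,
    generate_case,
    icp_refine,
    landmark_align,
    surface_cloud,
)

truth = RigidTransform.from_axis_angle([0.5, 0.2, 1.0], 22.0, [9.0, -5.0, 4.0])
case = generate_case(PhantomParams(seed=3, thickness_bias=0.7, true_transform=truth))

init = landmark_align(case.landmarks_mri, case.landmarks_ct)
src = surface_cloud(case.mri_volume, 10000, seed=0)
dst = surface_cloud(case.ct_volume, 10000, seed=1)
icp = icp_refine(src, dst, init.transform)

rot_err = icp.transform.geodesic_to(case.truth)
trans_err = np.linalg.norm(icp.transform.translation - case.truth.translation)
overlap = dsc_3d(case.mri_volume, case.ct_volume, icp.transform)

print(f"landmark init RMSD    : {init.rmsd_mm:.2f} mm (noisy landmarks)")
print(f"ICP                   : {icp.diagnostics.termination} after "
      f"{icp.diagnostics.n_iterations} iterations, "
      f"final RMS {icp.diagnostics.final_rms_distance_mm:.3f} mm")
print(f"recovered vs truth    : {rot_err:.2f} deg rotation, "
      f"{trans_err:.2f} mm translation error")
print(f"3D DSC                : {overlap.dsc:.3f}")
print(f"volumes (MRI, CT)     : {case.mri_volume.label_volume_mm3():.0f}, "
      f"{case.ct_volume.label_volume_mm3():.0f} mm^3")

# The pose is recovered to a fraction of a degree/millimetre, yet the 3D DSC
# is depressed: with thickness biased to 70%, the volumes cannot overlap well.
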