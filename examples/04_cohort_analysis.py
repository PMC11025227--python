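"""Cohort-level analysis: per-case DSC triplets and the volume correlation.

Runs the full two-track pipeline over a small seeded cohort with thickness
bias drawn from 0.5-0.9 and aggregates the per-case reports the way a
validation study would: mean 2D DSC (vs photo and vs gold render), mean 3D
DSC, and the Pearson correlation of paired cartilage volumes.
"""

from cartival import PipelineConfig, generate_cohort, run_cohort
from cartival.synthetic import CohortRanges

cohort = generate_cohort(6, CohortRanges(), seed=19)
report = run_cohort(cohort, PipelineConfig(seed=1))

print(f"{'case':10s} {'2D vs photo':>12s} {'2D vs CT':>10s} {'3D':>7s} "
      f"{'V_mri':>8s} {'V_ct':>8s}")
for c in report.per_case:
    print(f"{c.case_id:10s} {c.dsc2d_model_vs_photo:12.3f} "
          f"{c.dsc2d_model_vs_ctmodel:10.3f} {c.dsc3d:7.3f} "
          f"{c.volume_mri_mm3:8.0f} {c.volume_ct_mm3:8.0f}")
print(f"\nmean 2D DSC vs photo     : {report.mean_dsc2d_photo:.3f}")
print(f"mean 2D DSC vs CT render : {report.mean_dsc2d_ct:.3f}")
print(f"mean 3D DSC              : {report.mean_dsc3d:.3f}")
print(f"volume Pearson r (p)     : {report.pearson_r_volumes:.3f} "
      f"({report.pearson_p:.4f})")

# The signature this pipeline is built to expose: 2D agreement stays high
# while 3D agreement drops with thickness bias, and volumes stay strongly
# correlated -- the model is consistently, not randomly, too thin.
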