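"""Average cortical distance (d_avg) and its age trend on a synthetic cohort.

d_avg — the mean distance from the image origin to the outer cortical
surface — is the lever arm converting rotation angles into millimetres.
A spherical gray-matter shell of radius 65 mm must give d_avg close to 65;
a cohort generated with a known developmental slope must return it.
"""

import motionqc as mq
from motionqc.synth import PhantomConfig, simulate_cohort, synthetic_brain

_, _, shell = synthetic_brain(
    PhantomConfig(shape=(141, 141, 141), semi_axes_mm=(65.0, 65.0, 65.0),
                  shell_thickness_mm=3.0, contrast=0.0, texture_amplitude=0.0)
)
res = mq.average_cortical_distance(shell)
print(f"sphere shell, radius 65 mm: d_avg = {res.d_avg:.2f} mm "
      f"({res.surface_voxel_count} surface voxels)")

subjects, _ = simulate_cohort(n=40, age_range_years=(4, 18),
                              slope_mm_per_year=0.18, noise_sd_mm=0.5, seed=3)
pairs = [(age, mq.average_cortical_distance(s).d_avg) for age, s in subjects]
trend = mq.cohort_trend(pairs)
print(f"cohort of {trend.n}: recovered slope = {trend.slope_mm_per_year:.3f} "
      f"mm/year (generated with 0.18), Spearman rho = {trend.spearman_rho:.2f}, "
      f"p = {trend.spearman_p:.2g}")
print("The lever arm grows with age in development, so a fixed 65 mm slightly "
      "underestimates children's rotational displacement.")
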