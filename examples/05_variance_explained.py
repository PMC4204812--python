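"""Variance explained by motion-regressor sets, relative to the 24-parameter
Volterra expansion.

Injects known motion into a synthetic series and fits voxel-wise GLMs with
the complete / reduced realignment-parameter sets and the motion
fingerprint, reporting mean R^2 as a percentage of the volterra24 reference.
"""

import motionqc as mq
from motionqc.synth import (
    MotionSimConfig,
    PhantomConfig,
    simulate_fmri,
    simulate_motion,
    synthetic_brain,
)

brain, mask, _ = synthetic_brain(
    PhantomConfig(shape=(26, 26, 26), semi_axes_mm=(10, 9, 8),
                  shell_thickness_mm=2.5, texture_amplitude=0.3, seed=4)
)
params, _ = simulate_motion(
    MotionSimConfig(n_volumes=80, drift_sd_mm=0.07, drift_sd_rad=0.001,
                    spike_probability=0.05, seed=4)
)
series = simulate_fmri(brain, params, noise_sd=2.0, seed=4, spline_order=3)
glm_mask = mask.astype_mask()

# motion fingerprint traces come from the phantom replay of the same motion
phantom = mq.build_phantom(series, params, spline_order=3)
traces = mq.roi_traces(phantom, mq.derive_rois(mask))

designs = {sid: mq.build_design(params, sid)
           for sid in ("rps_complete", "rps_to", "rps_ro", "volterra24")}
designs["mfp_complete"] = mq.build_design(None, "mfp_complete", traces=traces)

fits = {sid: mq.fit_glm(series, d, mask=glm_mask) for sid, d in designs.items()}
ref = fits["volterra24"]
print(f"voxels in mask: {ref.n_voxels}, T = {params.volume_count}")
print(f"\nmean R^2 (volterra24 = {ref.mean_r2:.3f} = 100%):")
for sid, res in fits.items():
    pct = mq.percent_of_reference(res, ref)
    print(f"  {sid:13s}: R^2 = {res.mean_r2:.3f}  ({pct:6.1f}%)  K_eff = {res.df_num}")
print(
    "\nThe complete set explains more variance than either reduced set; the\n"
    "3-component fingerprint tracks the complete set closely with fewer\n"
    "regressors."
)
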