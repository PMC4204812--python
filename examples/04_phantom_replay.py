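"""Phantom replay: geometric signal change induced by a recorded trajectory.

Builds a motion-free phantom from the first volume of a (simulated) series,
re-applies the inverted motion transforms, and scores the mean absolute
signal change in 9 brain/non-brain interface ROIs — for the complete and
both reduced parameter sets.
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
    PhantomConfig(shape=(32, 32, 32), semi_axes_mm=(12, 11, 10),
                  shell_thickness_mm=3, texture_amplitude=0.3, seed=2)
)
# rotation arcs scaled to the phantom's ~12 mm radius so both parameter
# halves move the little brain's edge by comparable amounts
params, _ = simulate_motion(
    MotionSimConfig(n_volumes=40, drift_sd_mm=0.03, drift_sd_rad=0.005,
                    spike_probability=0.05, spike_amplitude_mm=(0.3, 0.8),
                    lever_arm_mm=12.0, seed=2)
)
series = simulate_fmri(brain, params, noise_sd=1.0, seed=2, spline_order=3)
rois = mq.derive_rois(mask)
print(f"derived {len(rois)} ROIs (8 corner-interface + 1 center)")

scores = {}
for pset in mq.PARAMETER_SETS:
    phantom = mq.build_phantom(series, params.reduced(pset), spline_order=3)
    traces = mq.roi_traces(phantom, rois)
    scores[pset] = mq.signal_change_score(traces, parameter_set=pset).score

ref = scores["complete"]
print(f"\nsignal-change score (complete set = {ref:.2f} = 100%):")
for pset, score in scores.items():
    print(f"  {pset:17s}: {score:8.2f}  ({100 * score / ref:6.1f}%)")
print(
    "\nNeither reduced set reproduces the complete-set signal change, and\n"
    "the split between them is trajectory-specific: translation dominates\n"
    "this run, while other trajectories push translation-only above 100%\n"
    "(rotation partially cancelling translation at the brain edge).\n"
    "Geometric replay only; susceptibility-by-motion effects are not modelled."
)
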