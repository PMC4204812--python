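"""Total displacement from a realignment trajectory, complete vs reduced sets.

Simulates a drifting head trajectory with a few discrete movements, converts
it to total displacement (mm) at the standard 65 mm cortical lever arm, and
shows how much of the motion each reduced parameter set captures.
"""

import numpy as np

import motionqc as mq
from motionqc.synth import MotionSimConfig, simulate_motion

params, spikes = simulate_motion(
    MotionSimConfig(n_volumes=200, spike_probability=0.03, seed=1)
)
print(f"trajectory: {params.volume_count} volumes, {len(spikes)} discrete movements")

for mode in ("absolute", "relative"):
    ref = np.median(mq.displacement_series(params, d_avg=65.0, mode=mode).values)
    print(f"\n{mode} motion (median of complete set: {ref:.3f} mm = 100%)")
    for pset in ("translation_only", "rotation_only"):
        med = np.median(
            mq.displacement_series(params, d_avg=65.0, mode=mode,
                                   parameter_set=pset).values
        )
        print(f"  {pset:17s}: {med:.3f} mm  ({100 * med / ref:6.1f}% of complete)")

disc = mq.sign_discordance(params)
print(
    f"\nsign discordance (same-axis shift vs rotation with opposite signs): "
    f"{disc.per_axis} of {disc.total_datapoints} volumes per axis"
)
print(
    "Reduced sets typically land well below 100%: neither translations nor\n"
    "rotations alone describe the trajectory the realignment recovered."
)
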