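"""Prescribe a moderate physical intensity for an older adult.

Karvonen target at 40% of heart rate reserve with age-predicted HRmax,
then a simulated stepping ramp test (start 80 steps/min, +5 every 20 s)
to find the stepping frequency that reaches the target.
"""

import numpy as np

from vmhrv import ProtocolParams, RampConfig, karvonen_target, ramp_test

params = ProtocolParams(age=67.0, hr_rest=62.0)  # HRmax = 208 - 0.7*67 = 161.1
target = karvonen_target(params)
print(f"age-predicted HRmax : {params.hr_max:.1f} bpm")
print(f"Karvonen target (40% HRR): {target:.2f} bpm")

# a participant whose HR rises roughly linearly with ramp time, plus noise
rng = np.random.default_rng(1)
t = np.arange(0.0, 400.0, 1.0)
hr = 70.0 + 0.2 * t + rng.normal(0, 1.5, t.size)
spm = ramp_test(np.column_stack([t, hr]), RampConfig(), target)
print(f"first stage reaching target: {spm:.0f} steps/min")

# The target sits strictly between resting and maximal HR; the ramp answer
# is always on the 80 + 5k steps/min grid of the protocol.
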