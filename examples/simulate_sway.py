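"""Generate sway trajectories from the named parameter presets.

Builds a 60 s center-of-mass-angle series for each data-generating
parameter set, at 100 Hz with measurement noise, and prints amplitude
summaries.  The printed SD is the stationary sway amplitude in radians:
it is set mostly by the insensitivity radius r (the dead zone the state
must leave before active feedback reacts), not by the noise level.
"""

import numpy as np

import ipcsway as ip

constants = ip.PhysicalConstants()  # 60 kg, COM 1 m above the ankle

for preset in ip.presets():
    traj = ip.simulate(preset.params, constants, duration=60.0, seed=1)
    series = ip.observe(ip.downsample(traj, 100.0), preset.params.eps,
                        mu=0.0, seed=2)
    v = series.values
    print(f"{preset.name:24s} sd={v.std():7.4f} rad   "
          f"range=[{v.min():7.3f}, {v.max():7.3f}]   n={len(series)}")
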