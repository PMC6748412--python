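"""Fit the model to a series stored as delimited text.

Writes a simulated trial to disk in the 2-column (time, value) layout,
reads it back, trims the first and last seconds (as one would for real
recordings, where trial initiation and termination contaminate the
ends), and runs a quick fit.  For real center-of-mass files use
SeriesFile to pick the value column by name or index, and derive the
pendulum length from standing height with com_height_from_stature.
"""

import tempfile
from pathlib import Path

import ipcsway as ip
from ipcsway.fit import DESettings

constants = ip.PhysicalConstants(mass=70.0,
                                 com_height=ip.com_height_from_stature(1.75))
preset = ip.get_preset("asai")
traj = ip.simulate(preset.params, constants, duration=20.0, seed=3)
series = ip.observe(ip.downsample(traj, 100.0), preset.params.eps, mu=0.2,
                    seed=4)

path = Path(tempfile.mkdtemp()) / "trial.csv"
ip.write_series(series, path)
loaded = ip.preprocess(ip.read_series(path), trim_head=100, trim_tail=100)
print(f"loaded {len(loaded)} samples at dt = {loaded.dt} s from {path}")

res = ip.fit(loaded, ip.ModelVariant.ISDDE,
             settings=DESettings(iterations=60, step_tol=40, seed=1,
                                 polish_maxfev=8000),
             constants=constants, restarts=1)
p = res.params
print(f"K={p.K:.3f} a={p.a:.3f} r={p.r:.3f} tau={p.tau:.3f} "
      f"sigma_w={p.sigma_w:.3f} mu={res.nuisances[0].mu:.3f}")
print("(quick-budget fit; see docs/methods.md for full settings)")
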