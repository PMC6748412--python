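"""AIC comparison of the nested model variants on synthetic data.

Generates data from the delay-free continuous model (SDE class: only
instantaneous stiffness and damping), fits all three variants, and
selects by AIC.  The full switching model cannot buy enough likelihood
with its extra parameters, so the simpler class wins -- the same
comparison applied per trial is how the model family is chosen on real
recordings.
"""

import ipcsway as ip
from ipcsway.fit import DESettings, default_bounds

constants = ip.PhysicalConstants()
gen = ip.IPCParameters(K=1.5, B=20.0, P=0.0, D=0.0, a=0.5, r=0.0,
                       tau=0.0, sigma_w=0.4, eps=1e-4)
traj = ip.simulate(gen, constants, duration=20.0, fine_dt=1e-4, seed=5)
series = ip.observe(ip.downsample(traj, 100.0), gen.eps, mu=0.0, seed=6)

fits = []
for variant in ip.ModelVariant:
    bounds = {k: v for k, v in {"K": (0.0, 3.0),
                                "tau": (0.01, 0.25)}.items()
              if k in default_bounds(variant)}
    res = ip.fit(series, variant, bounds=bounds,
                 settings=DESettings(iterations=60, step_tol=40, seed=2,
                                     polish_maxfev=6000),
                 constants=constants, restarts=1)
    fits.append(res)
    print(f"{variant.name:6s} -2lnL = {res.minus2ll:10.1f}   "
          f"k = {res.n_parameters:2d}   AIC = {res.aic:10.1f}")
print("selected:", ip.select_model(fits).name)
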