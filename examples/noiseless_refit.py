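"""Re-estimate all parameters from a deterministic trajectory.

The specification check of the estimator: simulate the "Asai et al."
parameter set without any noise (20 s from a 1 rad tilt), then refit the
full switching model from the 100 Hz series alone.  With clean data the
estimates should come back at the generating values to ~3 decimals
(B and D carry a small, known discretization bias), and the fitted noise
intensities collapse toward zero.  Takes a few minutes.
"""

import ipcsway as ip

result = ip.run_noiseless_check("Asai et al.", hz=100.0, duration=20.0,
                                de_iterations=3000, seed=0)
p = result.params
truth = ip.get_preset("Asai et al.").params
print(f"{'':8s}{'estimate':>12s}{'truth':>12s}")
for name in ("K", "B", "P", "D", "a", "r", "tau", "sigma_w"):
    print(f"{name:8s}{getattr(p, name):12.5f}{getattr(truth, name):12.5f}")
print(f"\n-2lnL = {result.minus2ll:.1f}  "
      f"({result.n_evaluations} likelihood evaluations)")
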