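import numpy as np
import pytest

import ipcsway as ip


@pytest.fixture(scope="session")
def constants():
    return ip.PhysicalConstants()


@pytest.fixture(scope="session")
def asai():
    return ip.get_preset("asai").params


@pytest.fixture(scope="session")
def noiseless_asai_100hz(asai, constants):
    """Deterministic 20 s trajectory from tilt 1 rad, sampled at 100 Hz."""
    traj = ip.simulate(asai, constants, duration=20.0, fine_dt=1e-5,
                       x0=1.0, xdot0=0.0, noiseless=True)
    return ip.downsample(traj, 100.0)


@pytest.fixture(scope="session")
def noisy_trials(asai, constants):
    """Three observed 30 s trials sharing the Asai et al. parameters."""
    root = np.random.SeedSequence(2024)
    trials = []
    for child in root.spawn(3):
        s1, s2 = child.spawn(2)
        traj = ip.simulate(asai, constants, duration=30.0, fine_dt=1e-4,
                           seed=np.random.default_rng(s1))
        trials.append(ip.observe(ip.downsample(traj, 100.0), asai.eps,
                                 mu=0.0, seed=np.random.default_rng(s2)))
    return trials
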