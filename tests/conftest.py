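import numpy as np
import pytest

from photodipole.photokinetics import PhotoswitchParams
from photodipole.membrane_circuit import MembraneCircuitParams
from photodipole.synthetic_data import (EnsembleDesign, GroupSpec, GeneratorTruth,
                                        gen_current_clamp_ensemble)


@pytest.fixture(scope="session")
def default_params():
    return PhotoswitchParams()


@pytest.fixture(scope="session")
def default_circuit():
    return MembraneCircuitParams()


@pytest.fixture(scope="session")
def default_truth():
    return GeneratorTruth()


@pytest.fixture(scope="session")
def small_cc_ensemble(default_truth):
    """Compact current-clamp ensemble: 10 uM at all four intensities."""
    groups = tuple(GroupSpec(10.0, i, 20.0, 8) for i in (27.0, 54.0, 79.0, 105.0))
    design = EnsembleDesign(groups=groups, seed=1234)
    return gen_current_clamp_ensemble(design, default_truth)


def rk4_ncis(protocol, params, n0, dt):
    """Independent fixed-step RK4 oracle for the cis-fraction rate equation."""
    ts = [0.0]
    ys = [n0]
    y = n0
    t_now = 0.0
    for dur, I in protocol.segments:
        def f(n):
            return params.kappa_TC * I * (1 - n) - (params.kappa_CT * I + params.gamma) * n
        n_steps = int(round(dur / dt))
        for _ in range(n_steps):
            k1 = f(y)
            k2 = f(y + 0.5 * dt * k1)
            k3 = f(y + 0.5 * dt * k2)
            k4 = f(y + dt * k3)
            y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            t_now += dt
            ts.append(t_now)
            ys.append(y)
    return np.asarray(ts), np.asarray(ys)
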