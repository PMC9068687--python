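import numpy as np
import pytest

import mrtphase as mp


@pytest.fixture(scope="session")
def gsp_spec():
    return mp.GSPSpec()


@pytest.fixture(scope="session")
def alif_spec():
    return mp.ALIFSpec()


@pytest.fixture(scope="session")
def hh_spec():
    return mp.HHSpec()


@pytest.fixture(scope="session")
def alif_cycle(alif_spec):
    return mp.alif_limit_cycle(alif_spec)


@pytest.fixture(scope="session")
def alif_mesh(alif_spec, alif_cycle):
    return mp.alif_phase_mesh(alif_spec, alif_cycle)


@pytest.fixture(scope="session")
def hh_cycle(hh_spec):
    return mp.hh_limit_cycle(hh_spec)


def classical_hh_euler(spec, V0, m, h, n, duration, dt):
    """Independent oracle: the 4-variable HH model, same explicit Euler step.

    The gate products of the 14-dim eps=0 system must track this solution
    (binomial-product manifold invariance of the diffusion approximation).
    """
    n_steps = int(round(duration / dt))
    V_out = np.empty(n_steps)
    V = V0
    for i in range(n_steps):
        am, bm, ah, bh, an, bn = mp.hh_rates(V)
        I_ion = (spec.gbar_Na * m**3 * h * (V - spec.V_Na)
                 + spec.gbar_K * n**4 * (V - spec.V_K)
                 + spec.g_L * (V - spec.V_L))
        V_next = V + dt * (spec.I_app - I_ion) / spec.C
        m += dt * (am * (1 - m) - bm * m)
        h += dt * (ah * (1 - h) - bh * h)
        n += dt * (an * (1 - n) - bn * n)
        V = V_next
        V_out[i] = V
    return V_out
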