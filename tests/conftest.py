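import numpy as np
import pytest

from tcskinetics import (
    CycleParams,
    TcsParams,
    get_preset,
    integrate_to_steady_state,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20140508)


@pytest.fixture(scope="session")
def cycle_low_params() -> CycleParams:
    """Low-affinity modification cycle: lambda = K_d/E_T = 1000."""
    return CycleParams(
        kin_on=10.0, kin_off=1.0, kin_cat=1.0,
        pho_on=10.0, pho_off=1.0, pho_cat=1.0,
        eff_on=1.0, eff_off=10.0,
        S_T=1.0, E_T=0.01, L_T=10.0,
    )


@pytest.fixture(scope="session")
def cycle_high_params() -> CycleParams:
    """High-affinity, saturated cycle: lambda = 1e-4, Km/S_T = 0.01."""
    return CycleParams(
        kin_on=2.0, kin_off=1.0, kin_cat=1.0,
        pho_on=2.0, pho_off=1.0, pho_cat=1.0,
        eff_on=100.0, eff_off=0.01,
        S_T=100.0, E_T=1.0, L_T=0.3,
    )


@pytest.fixture(scope="session")
def tcs_low_params() -> TcsParams:
    return get_preset("graded_low_affinity").params


@pytest.fixture(scope="session")
def tcs_high_params() -> TcsParams:
    return get_preset("ultrasensitive_high_affinity").params


@pytest.fixture(scope="session")
def nri_params() -> TcsParams:
    return get_preset("nri_like_autodephos").params


def random_state(rng, n, scale=1.0):
    return scale * rng.uniform(0.0, 1.0, size=n)


def ode_output(variant, params, **kw):
    """Free phosphorylated regulator/substrate at the full-model steady state."""
    res = integrate_to_steady_state(variant, params, **kw)
    return res.state.Sp if variant == "cycle" else res.state.Rp
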