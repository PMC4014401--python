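import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tcskinetics as tk
from tcskinetics.steady_state import BgParams, GkParams

from _oracles import bg_root_oracle, gk_fraction_oracle
from conftest import ode_output


# ---------------------------------------------------------------------------
# time-integration oracle
# ---------------------------------------------------------------------------


def test_one_way_flux_limits(cycle_low_params, tcs_high_params):
    """Without any dephosphorylation path the modified pool saturates."""
    p = cycle_low_params.replace(L_T=0.0)
    assert ode_output("cycle", p) / p.S_T == pytest.approx(1.0, abs=1e-3)
    p = tcs_high_params.replace(L_T=0.0, k_auto=0.0)
    assert ode_output("tcs", p) / p.R_T == pytest.approx(1.0, abs=1e-3)


def test_integration_deterministic_and_converged(tcs_low_params):
    p = tcs_low_params.replace(L_T=30.0)
    r1 = tk.integrate_to_steady_state("tcs", p)
    r2 = tk.integrate_to_steady_state("tcs", p)
    np.testing.assert_array_equal(r1.state.as_array(), r2.state.as_array())
    assert r1.residual_norm < 1e-9
    assert r1.method == "ode"


def test_integration_nonconvergence_raises(tcs_low_params):
    with pytest.raises(tk.ConvergenceError):
        tk.integrate_to_steady_state("tcs", tcs_low_params.replace(L_T=30.0), t_max=1.0)


def test_saturated_system_switches_off_above_transition(tcs_high_params):
    """Slightly above the transition point the regulator is dephosphorylated."""
    lstar = tk.transition_point(tcs_high_params)
    p = tcs_high_params.replace(L_T=1.3 * lstar)
    assert ode_output("tcs", p) / p.R_T < 0.1


# ---------------------------------------------------------------------------
# Batchelor-Goulian quadratic
# ---------------------------------------------------------------------------


def test_bg_quadratic_root_properties():
    assert tk.solve_bg_quadratic(BgParams(K1=2.0, K2=0.5, R_T=0.0)) == 0.0
    rng = np.random.default_rng(7)
    for _ in range(200):
        k1, k2, rt = np.exp(rng.uniform(np.log(1e-2), np.log(1e2), size=3))
        rp = tk.solve_bg_quadratic(BgParams(K1=k1, K2=k2, R_T=rt))
        assert 0.0 <= rp <= min(rt, k1) + 1e-12
        assert rp == pytest.approx(bg_root_oracle(k1, k2, rt), rel=1e-10, abs=1e-12)
    grid = np.linspace(0.0, 50.0, 200)
    vals = [tk.solve_bg_quadratic(BgParams(K1=3.0, K2=1.0, R_T=r)) for r in grid]
    assert np.all(np.diff(vals) >= -1e-12)


def test_bg_limiting_regimes():
    # plateau regime: linear rise up to a threshold equal to the plateau (K1)
    k1, k2 = 5.0, 0.05
    lo = tk.solve_bg_quadratic(BgParams(K1=k1, K2=k2, R_T=0.5))
    assert lo == pytest.approx(0.5, rel=0.05)
    hi = tk.solve_bg_quadratic(BgParams(K1=k1, K2=k2, R_T=50.0))
    assert hi == pytest.approx(k1, rel=0.05)
    # hyperbolic regime: half the asymptote at R_T = K2 >> K1
    k1, k2 = 0.5, 100.0
    mid = tk.solve_bg_quadratic(BgParams(K1=k1, K2=k2, R_T=k2))
    assert mid == pytest.approx(k1 / 2, rel=0.05)


def test_bg_matches_tcs_ode_on_seeded_grid(rng):
    """(K1, K2, R_T) grids realized as autodephosphorylating TCS systems agree
    with the full-ODE steady state in the BG limit H_T/R_T = 1e-3."""
    worst = 0.0
    for _ in range(30):
        rt = float(np.exp(rng.uniform(np.log(0.3), np.log(30.0))))
        k1 = rt * float(np.exp(rng.uniform(np.log(0.05), np.log(5.0))))
        k2 = rt * float(np.exp(rng.uniform(np.log(0.05), np.log(5.0))))
        p = _realize_bg(k1, k2, rt)
        rp_ode = ode_output("tcs", p)
        rp_alg = tk.solve_bg_quadratic(BgParams(K1=k1, K2=k2, R_T=rt))
        worst = max(worst, abs(rp_alg - rp_ode) / max(rp_ode, 1e-12))
    assert worst < 1e-2


def _realize_bg(k1, k2, rt):
    """TCS parameters whose reduced description has the given (K1, K2, R_T).

    Effector-free construction: the phosphatase side is pure regulator
    autodephosphorylation, so K1 = k_ap H_T/(k_auto D1) and
    K2 = k_ap Km_t/(pt_cat D1) with D1 = 1 + k_ap/pt_cat.
    """
    h_t = 1e-3 * rt
    k_ap = pt_cat = 1.0
    d1 = 1.0 + k_ap / pt_cat
    km_t = k2 * d1 * pt_cat / k_ap
    pt_off = 1.0
    k_auto = k_ap * h_t / (k1 * d1)
    return tk.TcsParams(
        k_ap=k_ap, pt_on=(pt_off + pt_cat) / km_t, pt_off=pt_off, pt_cat=pt_cat,
        ph_on=1.0, ph_off=1.0, ph_cat=1.0, eff_on=1.0, eff_off=1.0,
        R_T=rt, H_T=h_t, L_T=0.0, k_auto=k_auto,
    )


# ---------------------------------------------------------------------------
# Goldbeter-Koshland relation
# ---------------------------------------------------------------------------


def test_gk_symmetry_and_limits():
    p = GkParams(Vmax_kin=1.0, Vmax_pho=1.0, Km_kin=0.3, Km_pho=0.3, S_T=1.0)
    assert tk.solve_gk(p) == pytest.approx(0.5, abs=1e-12)
    # first-order limit: fraction set by the Vmax/Km ratios
    p = GkParams(Vmax_kin=2.0, Vmax_pho=3.0, Km_kin=500.0, Km_pho=200.0, S_T=1.0)
    want = (2.0 / 500.0) / (2.0 / 500.0 + 3.0 / 200.0)
    assert tk.solve_gk(p) == pytest.approx(want, abs=1e-3)
    # zero-order regime, 5% rate imbalance: exact root (hand-solved quadratic)
    p = GkParams(Vmax_kin=1.05, Vmax_pho=1.0, Km_kin=0.01, Km_pho=0.01, S_T=1.0)
    assert tk.solve_gk(p) == pytest.approx(0.84006, abs=1e-4)
    # deeper into zero order the same imbalance flips the pool almost completely
    p = GkParams(Vmax_kin=1.05, Vmax_pho=1.0, Km_kin=0.001, Km_pho=0.001, S_T=1.0)
    assert tk.solve_gk(p) > 0.9


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    st.floats(min_value=0.01, max_value=100.0),
    st.floats(min_value=0.01, max_value=100.0),
    st.floats(min_value=1e-3, max_value=1e3),
    st.floats(min_value=1e-3, max_value=1e3),
)
def test_gk_matches_bisection_oracle(vk, vp, jk, jp):
    """Closed-form root equals an independent bisection solve of the balance."""
    got = tk.solve_gk(GkParams(Vmax_kin=vk, Vmax_pho=vp, Km_kin=jk, Km_pho=jp, S_T=1.0))
    want = gk_fraction_oracle(vk, vp, jk, jp)
    assert got == pytest.approx(want, rel=1e-7, abs=1e-9)


# ---------------------------------------------------------------------------
# regime-specific reductions vs the ODE oracle
# ---------------------------------------------------------------------------


def test_cycle_low_affinity_vs_ode(cycle_low_params):
    p0 = cycle_low_params
    worst = 0.0
    for L in np.geomspace(0.5, 200.0, 10):
        p = p0.replace(L_T=float(L))
        frac_alg = tk.solve_cycle_low_affinity(p)
        frac_ode = ode_output("cycle", p) / p.S_T
        worst = max(worst, abs(frac_alg - frac_ode) / frac_ode)
    assert worst < 0.02


def test_cycle_low_affinity_limits_and_guard(cycle_low_params):
    assert tk.solve_cycle_low_affinity(cycle_low_params.replace(L_T=0.0)) == pytest.approx(1.0)
    bad = cycle_low_params.replace(eff_off=0.01)  # K_d/E_T = 1 -- not low affinity
    with pytest.warns(tk.RegimeWarning):
        tk.solve_cycle_low_affinity(bad)
    with pytest.raises(tk.RegimeError):
        tk.solve_cycle_low_affinity(bad, strict=True)


def test_cycle_high_affinity_vs_ode(cycle_high_params):
    p0 = cycle_high_params
    worst = 0.0
    for L in np.linspace(0.05, 0.95, 10):
        p = p0.replace(L_T=float(L))
        d = abs(tk.solve_cycle_high_affinity(p) - ode_output("cycle", p) / p.S_T)
        worst = max(worst, d)
    assert worst < 0.03
    assert tk.solve_cycle_high_affinity(p0.replace(L_T=0.0)) == pytest.approx(1.0, abs=1e-6)
    with pytest.raises(tk.RegimeError):
        tk.solve_cycle_high_affinity(p0.replace(L_T=2.0))  # L_T >= E_T


def test_tcs_low_affinity_vs_ode(tcs_low_params):
    worst = 0.0
    for L in np.geomspace(5.0, 5000.0, 8):
        for rt in (0.5, 1.0, 2.0):
            p = tcs_low_params.replace(L_T=float(L), R_T=rt, H_T=1e-3 * rt)
            rp_alg = tk.solve_tcs_low_affinity(p)
            rp_ode = ode_output("tcs", p)
            worst = max(worst, abs(rp_alg - rp_ode) / rp_ode)
    assert worst < 0.02


def test_tcs_low_affinity_large_effector_limit(tcs_low_params):
    vals = [tk.solve_tcs_low_affinity(tcs_low_params.replace(L_T=L))
            for L in (1e3, 1e4, 1e5)]
    assert vals[0] > vals[1] > vals[2]
    assert vals[2] < 1e-2 * tcs_low_params.R_T


def test_tcs_high_affinity_vs_ode(tcs_high_params):
    p0 = tcs_high_params
    worst = 0.0
    for L in np.linspace(0.004, 0.092, 12):
        p = p0.replace(L_T=float(L))
        d = abs(tk.solve_tcs_high_affinity(p) - ode_output("tcs", p)) / p.R_T
        worst = max(worst, d)
    assert worst < 0.03
    assert tk.solve_tcs_high_affinity(p0.replace(L_T=0.0)) == pytest.approx(p0.R_T, rel=1e-3)


def test_tcs_high_affinity_guards(tcs_high_params, nri_params):
    with pytest.raises(tk.RegimeError, match="k_auto"):
        tk.solve_tcs_high_affinity(nri_params)
    with pytest.raises(tk.RegimeError):
        tk.solve_tcs_high_affinity(tcs_high_params.replace(L_T=1.0))  # L_T >= H_T
    lowaff = tcs_high_params.replace(eff_on=0.001, L_T=0.01)
    with pytest.warns(tk.RegimeWarning):
        tk.solve_tcs_high_affinity(lowaff)


def test_bg_concentration_robustness_in_ode(tcs_low_params):
    """Rp at steady state is insensitive to the total kinase concentration.

    Holds when the HK phosphatase carries all dephosphorylation (k_auto = 0):
    autokinase and phosphatase fluxes are both proportional to free HK, so
    their balance pins Rp independently of H_T.
    """
    p = tcs_low_params.replace(L_T=200.0, R_T=2.0, k_auto=0.0)
    rps = [ode_output("tcs", p.replace(H_T=f * p.R_T)) for f in (1e-3, 1e-2)]
    assert abs(rps[1] - rps[0]) / rps[0] < 0.02
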