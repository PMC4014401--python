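import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tcskinetics as tk
from tcskinetics.model_core import (
    BASAL_SPECIES,
    CYCLE_SPECIES,
    TCS_SPECIES,
    ModelValidationError,
    _basal_rhs_arr,
    _cycle_rhs_arr,
    _tcs_rhs_arr,
    conserved_group_indices,
    loop_flux_imbalance,
    params_from_dict,
    params_to_dict,
)

from _oracles import basal_rhs_oracle, cycle_rhs_oracle, tcs_rhs_oracle


def _basal_params(tcs):
    return tk.BasalTcsParams(
        tcs=tcs,
        basal_autokinase=0.4,
        basal_transfer=0.7,
        basal_phosphatase=0.2,
        basal_transfer_binding=0.6,
        basal_phosphatase_binding=0.3,
        hp_eff_binding=0.5,
    )


@pytest.mark.parametrize(
    "variant,n",
    [("cycle", len(CYCLE_SPECIES)), ("tcs", len(TCS_SPECIES)), ("basal", len(BASAL_SPECIES))],
)
def test_rhs_matches_stoichiometry_oracle(variant, n, rng, cycle_low_params, tcs_low_params):
    """Hand-written derivatives equal the per-reaction stoichiometry x flux sum."""
    impl = {"cycle": _cycle_rhs_arr, "tcs": _tcs_rhs_arr, "basal": _basal_rhs_arr}[variant]
    oracle = {"cycle": cycle_rhs_oracle, "tcs": tcs_rhs_oracle, "basal": basal_rhs_oracle}[variant]
    params = {
        "cycle": cycle_low_params,
        "tcs": tcs_low_params.replace(k_auto=0.3),
        "basal": _basal_params(tcs_low_params.replace(k_auto=0.3)),
    }[variant]
    for _ in range(200):
        y = rng.uniform(0.0, 2.0, size=n)
        np.testing.assert_allclose(impl(y, params), oracle(y, params), rtol=1e-12, atol=1e-12)


@pytest.mark.parametrize("variant,n", [("cycle", 7), ("tcs", 8), ("basal", 11)])
def test_conserved_group_derivative_sums_vanish(variant, n, rng, cycle_low_params, tcs_low_params):
    """Within each conserved group the derivatives sum to zero to round-off."""
    impl = {"cycle": _cycle_rhs_arr, "tcs": _tcs_rhs_arr, "basal": _basal_rhs_arr}[variant]
    params = {
        "cycle": cycle_low_params,
        "tcs": tcs_low_params,
        "basal": _basal_params(tcs_low_params),
    }[variant]
    groups = conserved_group_indices(variant)
    ys = rng.uniform(0.0, 3.0, size=(1000, n))
    for y in ys:
        dy = impl(y, params)
        for g in groups:
            assert abs(dy[list(g)].sum()) < 1e-12


def test_empty_and_absent_pathway_derivatives(cycle_low_params, tcs_low_params):
    zero = np.zeros(7)
    assert np.all(_cycle_rhs_arr(zero, cycle_low_params) == 0.0)
    assert np.all(_tcs_rhs_arr(np.zeros(8), tcs_low_params) == 0.0)
    assert np.all(_basal_rhs_arr(np.zeros(11), _basal_params(tcs_low_params)) == 0.0)
    # no effector anywhere -> the effector-arm derivatives stay zero
    p = cycle_low_params.replace(L_T=0.0)
    y = np.array([0.4, 0.1, 0.2, 0.0, 0.05, 0.0, 0.0])  # EL = ELSp = L = 0
    dy = _cycle_rhs_arr(y, p)
    for name in ("EL", "ELSp", "L"):
        assert dy[CYCLE_SPECIES.index(name)] == 0.0
    # no dephosphorylation path -> Rp cannot decrease
    pt = tcs_low_params.replace(L_T=0.0, k_auto=0.0)
    y = np.array([0.02, 0.01, 0.0, 0.005, 0.0, 0.5, 0.3, 0.0])
    assert _tcs_rhs_arr(y, pt)[TCS_SPECIES.index("Rp")] >= 0.0


def test_state_validation_rejects_negative_concentration(tcs_low_params):
    with pytest.raises(ModelValidationError):
        tk.TcsState(H=-0.1, Hp=0, HL=0, HpR=0, HLRp=0, R=1, Rp=0, L=0)
    with pytest.raises(ModelValidationError):
        tk.TcsParams(**{**dataclasses.asdict(tcs_low_params), "pt_on": -1.0})


def test_basal_rhs_reduces_to_tcs(rng, tcs_low_params):
    """All basal factors zero: derivatives coincide exactly on shared species."""
    bp = tk.BasalTcsParams(tcs=tcs_low_params)
    for _ in range(50):
        y8 = rng.uniform(0.0, 2.0, size=8)
        y11 = np.concatenate([y8, np.zeros(3)])
        np.testing.assert_array_equal(_basal_rhs_arr(y11, bp)[:8], _tcs_rhs_arr(y8, tcs_low_params))
        assert np.all(_basal_rhs_arr(y11, bp)[8:] == 0.0)


def test_conservation_totals(cycle_low_params, tcs_low_params):
    p = cycle_low_params
    s = tk.CycleState.initial(p)
    assert tk.conservation_totals(s, "cycle") == (p.S_T, p.E_T, p.L_T)
    # a hand-built state with one ternary complex enters all three sums
    s2 = tk.CycleState(S=0.5, Sp=0.2, E=0.0, EL=0.0, ES=0.0, ELSp=0.01, L=9.99)
    sub, enz, eff = tk.conservation_totals(s2, "cycle")
    assert sub == pytest.approx(0.71)
    assert enz == pytest.approx(0.01)
    assert eff == pytest.approx(10.0)
    with pytest.raises(ModelValidationError):
        tk.conservation_totals(s2, "tcs")
    # totals are preserved along an integration
    res = tk.integrate_to_steady_state("tcs", tcs_low_params.replace(L_T=50.0))
    tot = tk.conservation_totals(res.state, "tcs")
    for got, want in zip(tot, (tcs_low_params.R_T, tcs_low_params.H_T, 50.0)):
        assert abs(got - want) <= 1e-8 * max(want, 1.0)


def test_two_compartment_rescale_identity_and_roundtrip(tcs_high_params):
    ctx1 = tk.CompartmentContext(volume_ratio=1.0)
    assert tk.two_compartment_rescale(tcs_high_params, ctx1) == tcs_high_params
    # amount basis is volume-free
    ctx_a = tk.CompartmentContext(volume_ratio=3.0, basis="amount")
    assert tk.two_compartment_rescale(tcs_high_params, ctx_a) == tcs_high_params
    p2 = tk.two_compartment_rescale(tcs_high_params, tk.CompartmentContext(2.0))
    p3 = tk.two_compartment_rescale(p2, tk.CompartmentContext(0.5))
    for f in ("eff_on", "L_T", "K_d"):
        assert getattr(p3, f) == pytest.approx(getattr(tcs_high_params, f), rel=1e-12)
    # first-order rates untouched
    assert p2.k_ap == tcs_high_params.k_ap and p2.pt_cat == tcs_high_params.pt_cat
    with pytest.raises(ModelValidationError):
        tk.CompartmentContext(volume_ratio=0.0)


def test_two_compartment_affinity_condition_flips(tcs_high_params):
    """Periplasmic sensing (alpha > 1) favors the high-affinity condition,
    dilute extracellular sensing (alpha < 1) suppresses it."""
    p = tcs_high_params.replace(eff_on=1.0 / 0.003, eff_off=1.0)  # K_d/H_T = 0.03
    assert tk.classify_regime(p).label == "intermediate"
    p_peri = tk.two_compartment_rescale(p, tk.CompartmentContext(4.0))
    assert tk.classify_regime(p_peri).label == "high_affinity_ultrasensitive"
    p_ext = tk.two_compartment_rescale(p, tk.CompartmentContext(0.1))
    assert tk.classify_regime(p_ext).label == "intermediate"
    assert p_ext.relative_affinity > p.relative_affinity


def test_volume_ratio_from_periplasmic_fraction():
    assert tk.volume_ratio_from_periplasmic_fraction(0.4) == pytest.approx(1.5)
    assert tk.volume_ratio_from_periplasmic_fraction(0.2) == pytest.approx(4.0)
    with pytest.raises(ModelValidationError):
        tk.volume_ratio_from_periplasmic_fraction(1.2)


def test_loop_consistency(tcs_low_params):
    helper_off = tk.consistent_hp_eff_off(
        tk.BasalTcsParams(tcs=tcs_low_params, basal_autokinase=0.5, hp_eff_binding=0.8)
    )
    assert helper_off == pytest.approx(0.8 * tcs_low_params.eff_off / 0.5)
    consistent = tk.BasalTcsParams(
        tcs=tcs_low_params, basal_autokinase=0.5, hp_eff_binding=0.8, hp_eff_off=helper_off
    )
    assert loop_flux_imbalance(consistent) < 1e-12
    with pytest.warns(UserWarning, match="cycle flux"):
        tk.BasalTcsParams(
            tcs=tcs_low_params, basal_autokinase=0.5, hp_eff_binding=0.8, hp_eff_off=10 * helper_off
        )


def test_params_serialization_roundtrip(tmp_path, tcs_low_params, cycle_low_params):
    for params, suffix in [
        (tcs_low_params, "json"),
        (cycle_low_params, "yaml"),
        (_basal_params(tcs_low_params), "json"),
    ]:
        path = tmp_path / f"p.{suffix}"
        tk.dump_params(params, path)
        assert tk.load_params(path) == params
    d = params_to_dict(tcs_low_params)
    assert d["units"]["pt_on"] == "1/(uM*min)"
    d["bogus_key"] = 1.0
    with pytest.raises(ModelValidationError, match="unknown keys"):
        params_from_dict(d)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=5.0), min_size=8, max_size=8))
def test_tcs_conservation_property(y):
    """Conserved-group derivative sums vanish for arbitrary nonnegative states."""
    p = tk.TcsParams(
        k_ap=0.7, pt_on=3.0, pt_off=0.5, pt_cat=2.0, ph_on=4.0, ph_off=0.2, ph_cat=1.5,
        eff_on=1.1, eff_off=0.9, R_T=1.0, H_T=0.1, L_T=0.5, k_auto=0.2,
    )
    dy = _tcs_rhs_arr(np.asarray(y), p)
    for g in conserved_group_indices("tcs"):
        assert abs(dy[list(g)].sum()) < 1e-10
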