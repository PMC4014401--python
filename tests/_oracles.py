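"""Independent oracles for the test suite.

The right-hand-side oracle assembles each model from an explicit list of
elementary irreversible reactions (stoichiometry dictionary + mass-action
flux), independently of the hand-written derivative expressions in the
package.  The Goldbeter-Koshland oracle solves the flux-balance relation by
bracketing bisection instead of the closed-form root.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from tcskinetics.model_core import BASAL_SPECIES, CYCLE_SPECIES, TCS_SPECIES


def _assemble(reactions, species):
    idx = {s: i for i, s in enumerate(species)}

    def rhs(y, params):
        out = np.zeros(len(species))
        s = {name: y[i] for name, i in idx.items()}
        for stoich, rate in reactions(params):
            v = rate(s)
            for name, coef in stoich.items():
                out[idx[name]] += coef * v
        return out

    return rhs


def _cycle_reactions(p):
    return [
        ({"E": -1, "S": -1, "ES": +1}, lambda s, p=p: p.kin_on * s["E"] * s["S"]),
        ({"ES": -1, "E": +1, "S": +1}, lambda s, p=p: p.kin_off * s["ES"]),
        ({"ES": -1, "E": +1, "Sp": +1}, lambda s, p=p: p.kin_cat * s["ES"]),
        ({"E": -1, "L": -1, "EL": +1}, lambda s, p=p: p.eff_on * s["E"] * s["L"]),
        ({"EL": -1, "E": +1, "L": +1}, lambda s, p=p: p.eff_off * s["EL"]),
        ({"EL": -1, "Sp": -1, "ELSp": +1}, lambda s, p=p: p.pho_on * s["EL"] * s["Sp"]),
        ({"ELSp": -1, "EL": +1, "Sp": +1}, lambda s, p=p: p.pho_off * s["ELSp"]),
        ({"ELSp": -1, "EL": +1, "S": +1}, lambda s, p=p: p.pho_cat * s["ELSp"]),
    ]


def _tcs_reactions(p):
    return [
        ({"H": -1, "Hp": +1}, lambda s, p=p: p.k_ap * s["H"]),
        ({"Hp": -1, "R": -1, "HpR": +1}, lambda s, p=p: p.pt_on * s["Hp"] * s["R"]),
        ({"HpR": -1, "Hp": +1, "R": +1}, lambda s, p=p: p.pt_off * s["HpR"]),
        ({"HpR": -1, "H": +1, "Rp": +1}, lambda s, p=p: p.pt_cat * s["HpR"]),
        ({"H": -1, "L": -1, "HL": +1}, lambda s, p=p: p.eff_on * s["H"] * s["L"]),
        ({"HL": -1, "H": +1, "L": +1}, lambda s, p=p: p.eff_off * s["HL"]),
        ({"HL": -1, "Rp": -1, "HLRp": +1}, lambda s, p=p: p.ph_on * s["HL"] * s["Rp"]),
        ({"HLRp": -1, "HL": +1, "Rp": +1}, lambda s, p=p: p.ph_off * s["HLRp"]),
        ({"HLRp": -1, "HL": +1, "R": +1}, lambda s, p=p: p.ph_cat * s["HLRp"]),
        ({"Rp": -1, "R": +1}, lambda s, p=p: p.k_auto * s["Rp"]),
    ]


def _basal_reactions(p):
    t = p.tcs
    off_p = p.effective_hp_eff_off
    return _tcs_reactions(t) + [
        ({"HL": -1, "HpL": +1}, lambda s: p.basal_autokinase * t.k_ap * s["HL"]),
        ({"HpL": -1, "R": -1, "HpLR": +1},
         lambda s: p.basal_transfer_binding * t.pt_on * s["HpL"] * s["R"]),
        ({"HpLR": -1, "HpL": +1, "R": +1}, lambda s: t.pt_off * s["HpLR"]),
        ({"HpLR": -1, "HL": +1, "Rp": +1}, lambda s: p.basal_transfer * t.pt_cat * s["HpLR"]),
        ({"H": -1, "Rp": -1, "HRp": +1},
         lambda s: p.basal_phosphatase_binding * t.ph_on * s["H"] * s["Rp"]),
        ({"HRp": -1, "H": +1, "Rp": +1}, lambda s: t.ph_off * s["HRp"]),
        ({"HRp": -1, "H": +1, "R": +1}, lambda s: p.basal_phosphatase * t.ph_cat * s["HRp"]),
        ({"Hp": -1, "L": -1, "HpL": +1},
         lambda s: p.hp_eff_binding * t.eff_on * s["Hp"] * s["L"]),
        ({"HpL": -1, "Hp": +1, "L": +1}, lambda s: off_p * s["HpL"]),
    ]


cycle_rhs_oracle = _assemble(lambda p: _cycle_reactions(p), CYCLE_SPECIES)
tcs_rhs_oracle = _assemble(lambda p: _tcs_reactions(p), TCS_SPECIES)


def basal_rhs_oracle(y, params):
    return _assemble(lambda p: _basal_reactions(p), BASAL_SPECIES)(y, params)


def gk_fraction_oracle(Vk, Vp, Jk, Jp):
    """Bisection root of Vk (1-x)/(Jk+1-x) = Vp x/(Jp+x) on [0, 1]."""

    def f(x):
        return Vk * (1 - x) / (Jk + 1 - x) - Vp * x / (Jp + x)

    if f(0.0) <= 0:
        return 0.0
    if f(1.0 - 1e-15) >= 0:
        return 1.0
    return brentq(f, 0.0, 1.0 - 1e-15, xtol=1e-14)


def bg_root_oracle(K1, K2, R_T):
    """Bisection root of x^2 - (R_T+K1+K2)x + K1*R_T on [0, min(R_T, K1)]."""

    def f(x):
        return x * x - (R_T + K1 + K2) * x + K1 * R_T

    hi = min(R_T, K1)
    if hi == 0.0:
        return 0.0
    if f(hi) >= 0.0:
        return hi
    return brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-14)
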