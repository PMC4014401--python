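"""Mass-action cores for bifunctional-kinase signaling models.

Three model variants share a common design: a converter enzyme whose two
opposing activities (phosphorylating and dephosphorylating) are partitioned
between its free and effector-bound forms, so that an allosteric effector
reciprocally inhibits one activity while activating the other.

* ``cycle`` -- a covalent modification cycle in which a bifunctional enzyme E
  phosphorylates substrate S and, once effector-bound (EL), dephosphorylates
  Sp.  The minimal setting in which reciprocal regulation can produce
  zero-order ultrasensitivity.
* ``tcs`` -- a classical two-component system: the free histidine kinase H
  autophosphorylates (ATP lumped into ``k_ap``) and transfers the phosphoryl
  group to the response regulator R, while the effector-bound form HL carries
  the phosphatase activity toward Rp.  An optional first-order
  autodephosphorylation of Rp (``k_auto``) models intrinsic RR phosphatase
  activity (e.g. NRI-P, half-life minutes).
* ``basal`` -- the tcs variant extended with basal (effector-independent or
  phosphorylation-state crossed) activities: autophosphorylation of HL,
  phosphotransfer from the phosphorylated effector-bound form HpL, phosphatase
  activity of free H, and effector binding to Hp.

Units are uM and minutes throughout the concentration basis; second-order
rate constants are uM^-1 min^-1.  An amount basis (pmol, pmol^-1 min^-1) is
supported for two-compartment bookkeeping, see :func:`two_compartment_rescale`.

State vectors carry every species explicitly; the conservation laws are
diagnostic invariants, not eliminations.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "CycleParams",
    "CycleState",
    "TcsParams",
    "TcsState",
    "BasalTcsParams",
    "BasalTcsState",
    "CompartmentContext",
    "CYCLE_SPECIES",
    "TCS_SPECIES",
    "BASAL_SPECIES",
    "cycle_rhs",
    "tcs_rhs",
    "basal_tcs_rhs",
    "conservation_totals",
    "two_compartment_rescale",
    "volume_ratio_from_periplasmic_fraction",
    "loop_flux_imbalance",
    "consistent_hp_eff_off",
    "params_to_dict",
    "params_from_dict",
    "load_params",
    "dump_params",
]

CYCLE_SPECIES = ("S", "Sp", "E", "EL", "ES", "ELSp", "L")
TCS_SPECIES = ("H", "Hp", "HL", "HpR", "HLRp", "R", "Rp", "L")
BASAL_SPECIES = TCS_SPECIES + ("HpL", "HpLR", "HRp")


class ModelValidationError(ValueError):
    """Raised when parameters or states violate their physical constraints."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ModelValidationError(msg)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CycleParams:
    """Rate constants and totals for the covalent modification cycle.

    ``kin_*`` describe kinase-form substrate binding/turnover
    (E + S <-> ES -> E + Sp), ``pho_*`` phosphatase-form turnover of modified
    substrate (EL + Sp <-> ELSp -> EL + S) and ``eff_*`` effector binding
    (E + L <-> EL).  Totals ``S_T``, ``E_T``, ``L_T`` are in uM.
    """

    kin_on: float
    kin_off: float
    kin_cat: float
    pho_on: float
    pho_off: float
    pho_cat: float
    eff_on: float
    eff_off: float
    S_T: float
    E_T: float
    L_T: float

    def __post_init__(self) -> None:
        for name in ("kin_on", "pho_on", "eff_on"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        for name in ("kin_off", "kin_cat", "pho_off", "pho_cat", "eff_off"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        for name in ("S_T", "E_T", "L_T"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        for name in ("Km_K", "Km_P", "K_d"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v > 0, f"derived {name} must be finite and > 0")

    # derived Michaelis and dissociation constants
    @property
    def Km_K(self) -> float:
        """Michaelis constant of the kinase activity (uM)."""
        return (self.kin_off + self.kin_cat) / self.kin_on

    @property
    def Km_P(self) -> float:
        """Michaelis constant of the phosphatase activity (uM)."""
        return (self.pho_off + self.pho_cat) / self.pho_on

    @property
    def K_d(self) -> float:
        """Dissociation constant of the enzyme-effector complex (uM)."""
        return self.eff_off / self.eff_on

    @property
    def relative_affinity(self) -> float:
        """lambda = K_d / E_T; large means low-affinity effector."""
        _require(self.E_T > 0, "relative_affinity undefined for E_T = 0")
        return self.K_d / self.E_T

    @property
    def stoichiometric_binding(self) -> float:
        """E_T / K_d; >> 1 means near-complete effector sequestration."""
        return self.E_T / self.K_d

    def replace(self, **kw) -> "CycleParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class TcsParams:
    """Rate constants and totals for the reciprocally regulated TCS.

    ``k_ap`` is the autophosphorylation rate of free HK (ATP lumped);
    ``pt_*`` the phosphotransfer complex (Hp + R <-> HpR -> H + Rp),
    ``ph_*`` the phosphatase complex (HL + Rp <-> HLRp -> HL + R),
    ``eff_*`` effector binding to free HK, and ``k_auto`` the first-order
    autodephosphorylation of Rp (0 disables it).
    """

    k_ap: float
    pt_on: float
    pt_off: float
    pt_cat: float
    ph_on: float
    ph_off: float
    ph_cat: float
    eff_on: float
    eff_off: float
    R_T: float
    H_T: float
    L_T: float
    k_auto: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pt_on", "ph_on", "eff_on"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        for name in ("k_ap", "pt_off", "pt_cat", "ph_off", "ph_cat", "eff_off", "k_auto"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        for name in ("R_T", "H_T", "L_T"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        for name in ("Km_t", "Km_p", "K_d"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v > 0, f"derived {name} must be finite and > 0")

    @property
    def Km_t(self) -> float:
        """Michaelis constant of the phosphotransfer activity (uM)."""
        return (self.pt_off + self.pt_cat) / self.pt_on

    @property
    def Km_p(self) -> float:
        """Michaelis constant of the phosphatase activity (uM)."""
        return (self.ph_off + self.ph_cat) / self.ph_on

    @property
    def K_d(self) -> float:
        return self.eff_off / self.eff_on

    @property
    def relative_affinity(self) -> float:
        _require(self.H_T > 0, "relative_affinity undefined for H_T = 0")
        return self.K_d / self.H_T

    @property
    def stoichiometric_binding(self) -> float:
        return self.H_T / self.K_d

    def replace(self, **kw) -> "TcsParams":
        return dataclasses.replace(self, **kw)

    def with_km(self, Km_t: float | None = None, Km_p: float | None = None) -> "TcsParams":
        """Return params with Michaelis constants set by adjusting on-rates.

        Keeps the off- and catalytic rates fixed, so ``Km = (off + cat)/on``
        holds with the requested value.  Convenient for fitting workflows that
        treat the Michaelis constants as free parameters.
        """
        kw = {}
        if Km_t is not None:
            _require(Km_t > 0, "Km_t must be > 0")
            kw["pt_on"] = (self.pt_off + self.pt_cat) / Km_t
        if Km_p is not None:
            _require(Km_p > 0, "Km_p must be > 0")
            kw["ph_on"] = (self.ph_off + self.ph_cat) / Km_p
        return self.replace(**kw)


@dataclass(frozen=True)
class BasalTcsParams:
    """TCS parameters extended with basal-activity scale factors.

    The basal factors scale the catalytic rates of the crossed pathways:
    ``basal_autokinase`` (phi_a) scales ``k_ap`` on HL -> HpL,
    ``basal_transfer`` (phi_t) scales ``pt_cat`` on the HpL transfer path and
    ``basal_phosphatase`` (phi_p) scales ``ph_cat`` on the effector-free
    phosphatase path H + Rp.  Binding-scale factors multiply the association
    rates of those paths: ``basal_transfer_binding`` (delta, HpL + R),
    ``basal_phosphatase_binding`` (eps, H + Rp) and ``hp_eff_binding`` (gamma,
    Hp + L).  ``hp_eff_off`` is the dissociation rate of the Hp-effector
    complex; if None it is derived from the loop-consistency condition
    ``hp_eff_off = gamma * eff_off / phi_a`` (see :func:`consistent_hp_eff_off`),
    which prevents a net steady flux around the binding/phosphorylation square.
    """

    tcs: TcsParams
    basal_autokinase: float = 0.0
    basal_transfer: float = 0.0
    basal_phosphatase: float = 0.0
    basal_transfer_binding: float = 0.0
    basal_phosphatase_binding: float = 0.0
    hp_eff_binding: float = 0.0
    hp_eff_off: float | None = None
    check_loop_consistency: bool = True

    def __post_init__(self) -> None:
        for name in (
            "basal_autokinase",
            "basal_transfer",
            "basal_phosphatase",
            "basal_transfer_binding",
            "basal_phosphatase_binding",
            "hp_eff_binding",
        ):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        if self.hp_eff_off is not None:
            _require(self.hp_eff_off >= 0, "hp_eff_off must be >= 0")
        if self.check_loop_consistency:
            imb = loop_flux_imbalance(self)
            if imb > 1e-9:
                warnings.warn(
                    "basal parameter set admits a net steady cycle flux around the "
                    f"H/Hp/HL/HpL square (relative imbalance {imb:.3g}); consider "
                    "hp_eff_off=consistent_hp_eff_off(...)",
                    stacklevel=2,
                )

    @property
    def effective_hp_eff_off(self) -> float:
        if self.hp_eff_off is not None:
            return self.hp_eff_off
        return consistent_hp_eff_off(self)

    def replace(self, **kw) -> "BasalTcsParams":
        return dataclasses.replace(self, **kw)


def consistent_hp_eff_off(p: BasalTcsParams) -> float:
    """Hp-effector dissociation rate that nulls the steady loop flux.

    Around the square H -> Hp -> HpL -> HL -> H (autophosphorylation up each
    side, effector binding across), the cycle condition (product of clockwise
    rate constants equal to the counter-clockwise product, with a common
    return edge for the two dephosphorylation directions) requires

        hp_eff_off = gamma * eff_off / phi_a

    equivalently K_d(Hp) = K_d / phi_a: a reduced basal autokinase activity
    on HL goes together with proportionally weaker effector binding to the
    already-phosphorylated kinase.
    """
    gamma = p.hp_eff_binding
    if gamma == 0.0:
        return 0.0
    _require(p.basal_autokinase > 0, "hp_eff_off underdetermined: gamma > 0 needs basal_autokinase > 0")
    return gamma * p.tcs.eff_off / p.basal_autokinase


def loop_flux_imbalance(p: BasalTcsParams) -> float:
    """Relative mismatch of the cycle condition on the H/Hp/HL/HpL square.

    Returns |cw - ccw| / max(cw, ccw) of the Kolmogorov rate products for the
    loop, evaluated on the effector-only subsystem at unit free-effector
    concentration.  0 means no net steady cycling.  Degenerate loops (either
    autophosphorylation edge absent, or Hp unable to bind effector) cannot
    cycle and report 0.
    """
    t = p.tcs
    gamma = p.hp_eff_binding
    phi_a = p.basal_autokinase
    if gamma == 0.0 or phi_a == 0.0 or t.k_ap == 0.0:
        return 0.0
    off_p = p.hp_eff_off if p.hp_eff_off is not None else consistent_hp_eff_off(p)
    cw = t.k_ap * (gamma * t.eff_on) * t.eff_off
    ccw = t.eff_on * (phi_a * t.k_ap) * off_p
    top = max(cw, ccw)
    if top == 0.0:
        return 0.0
    return abs(cw - ccw) / top


@dataclass(frozen=True)
class CompartmentContext:
    """Volume bookkeeping for effector sensing in a separate compartment.

    ``volume_ratio`` is alpha = V_cyt / V_ext, the ratio of the cytosolic
    volume to the periplasmic (or extracellular) volume in which the effector
    is measured.  ``basis`` selects whether quantities are concentrations
    (uM) or average molecule amounts (pmol); amount-based equations are
    volume-ratio free, so rescaling acts only on the concentration basis.
    """

    volume_ratio: float
    basis: str = "concentration"

    def __post_init__(self) -> None:
        _require(self.volume_ratio > 0, "volume_ratio must be > 0")
        _require(self.basis in ("concentration", "amount"), "basis must be 'concentration' or 'amount'")


def volume_ratio_from_periplasmic_fraction(fraction: float) -> float:
    """alpha = V_cyt/V_peri for a periplasm occupying ``fraction`` of the cell.

    A periplasmic volume fraction of 20-40% of the total cell volume gives
    alpha between 4 and 1.5.
    """
    _require(0 < fraction < 1, "periplasmic fraction must be in (0, 1)")
    return (1.0 - fraction) / fraction


def two_compartment_rescale(params: TcsParams, ctx: CompartmentContext) -> TcsParams:
    """Re-express effector-side quantities of a two-compartment TCS.

    The catalytic reactions happen in the cytosol while effector binding is
    sensed in the periplasm/extracellular space.  In the amount basis the
    mass balances are volume-free and the parameters are returned unchanged.
    In the concentration basis, a periplasmic effector at concentration c
    behaves like a cytosolic effector at concentration c/alpha, so the
    effector-side second-order rate and totals rescale:

        eff_on -> alpha * eff_on      (K_d -> K_d / alpha)
        L_T    -> L_T / alpha

    First-order rates and the cytosolic reactions are untouched.  Composing
    with the reciprocal ratio inverts the transformation.  Since the
    high-affinity condition reads K_d/alpha << H_T, alpha > 1 (periplasmic
    sensing) favors ultrasensitivity while alpha < 1 (dilute extracellular
    sensing) suppresses it.
    """
    a = ctx.volume_ratio
    if ctx.basis == "amount" or a == 1.0:
        return params
    return params.replace(eff_on=params.eff_on * a, L_T=params.L_T / a)


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------


def _check_state(values: Iterable[float], names: tuple[str, ...]) -> None:
    for n, v in zip(names, values):
        _require(v >= 0, f"concentration {n} must be >= 0 (got {v})")


@dataclass(frozen=True)
class CycleState:
    S: float
    Sp: float
    E: float
    EL: float
    ES: float
    ELSp: float
    L: float

    def __post_init__(self) -> None:
        _check_state(self.as_array(), CYCLE_SPECIES)

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.Sp, self.E, self.EL, self.ES, self.ELSp, self.L])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CycleState":
        return cls(*map(float, y))

    @classmethod
    def initial(cls, p: CycleParams) -> "CycleState":
        """Default start: all protein free and unmodified, effector free."""
        return cls(S=p.S_T, Sp=0.0, E=p.E_T, EL=0.0, ES=0.0, ELSp=0.0, L=p.L_T)


@dataclass(frozen=True)
class TcsState:
    H: float
    Hp: float
    HL: float
    HpR: float
    HLRp: float
    R: float
    Rp: float
    L: float

    def __post_init__(self) -> None:
        _check_state(self.as_array(), TCS_SPECIES)

    def as_array(self) -> np.ndarray:
        return np.array([self.H, self.Hp, self.HL, self.HpR, self.HLRp, self.R, self.Rp, self.L])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "TcsState":
        return cls(*map(float, y))

    @classmethod
    def initial(cls, p: TcsParams) -> "TcsState":
        return cls(H=p.H_T, Hp=0.0, HL=0.0, HpR=0.0, HLRp=0.0, R=p.R_T, Rp=0.0, L=p.L_T)


@dataclass(frozen=True)
class BasalTcsState:
    H: float
    Hp: float
    HL: float
    HpR: float
    HLRp: float
    R: float
    Rp: float
    L: float
    HpL: float = 0.0
    HpLR: float = 0.0
    HRp: float = 0.0

    def __post_init__(self) -> None:
        _check_state(self.as_array(), BASAL_SPECIES)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.H, self.Hp, self.HL, self.HpR, self.HLRp, self.R, self.Rp, self.L,
             self.HpL, self.HpLR, self.HRp]
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "BasalTcsState":
        return cls(*map(float, y))

    @classmethod
    def initial(cls, p: BasalTcsParams) -> "BasalTcsState":
        t = p.tcs
        return cls(H=t.H_T, Hp=0.0, HL=0.0, HpR=0.0, HLRp=0.0, R=t.R_T, Rp=0.0, L=t.L_T)


# ---------------------------------------------------------------------------
# right-hand sides (hand-written mass action; tests check them against an
# independently assembled stoichiometry-matrix x flux oracle)
# ---------------------------------------------------------------------------


def _cycle_rhs_arr(y: np.ndarray, p: CycleParams) -> np.ndarray:
    S, Sp, E, EL, ES, ELSp, L = y
    v_kb = p.kin_on * E * S - p.kin_off * ES          # E + S <-> ES
    v_kc = p.kin_cat * ES                              # ES -> E + Sp
    v_eb = p.eff_on * E * L - p.eff_off * EL           # E + L <-> EL
    v_pb = p.pho_on * EL * Sp - p.pho_off * ELSp       # EL + Sp <-> ELSp
    v_pc = p.pho_cat * ELSp                            # ELSp -> EL + S
    return np.array(
        [
            -v_kb + v_pc,          # S
            v_kc - v_pb,           # Sp
            -v_kb + v_kc - v_eb,   # E
            v_eb - v_pb + v_pc,    # EL
            v_kb - v_kc,           # ES
            v_pb - v_pc,           # ELSp
            -v_eb,                 # L
        ]
    )


def cycle_rhs(state: CycleState, params: CycleParams) -> np.ndarray:
    """Time derivatives (uM/min) of the modification-cycle species."""
    return _cycle_rhs_arr(state.as_array(), params)


def _tcs_rhs_arr(y: np.ndarray, p: TcsParams) -> np.ndarray:
    H, Hp, HL, HpR, HLRp, R, Rp, L = y
    v_ap = p.k_ap * H                                  # H -> Hp
    v_tb = p.pt_on * Hp * R - p.pt_off * HpR           # Hp + R <-> HpR
    v_tc = p.pt_cat * HpR                              # HpR -> H + Rp
    v_eb = p.eff_on * H * L - p.eff_off * HL           # H + L <-> HL
    v_pb = p.ph_on * HL * Rp - p.ph_off * HLRp         # HL + Rp <-> HLRp
    v_pc = p.ph_cat * HLRp                             # HLRp -> HL + R
    v_au = p.k_auto * Rp                               # Rp -> R
    return np.array(
        [
            -v_ap - v_eb + v_tc,   # H
            v_ap - v_tb,           # Hp
            v_eb - v_pb + v_pc,    # HL
            v_tb - v_tc,           # HpR
            v_pb - v_pc,           # HLRp
            -v_tb + v_pc + v_au,   # R
            v_tc - v_pb - v_au,    # Rp
            -v_eb,                 # L
        ]
    )


def tcs_rhs(state: TcsState, params: TcsParams) -> np.ndarray:
    """Time derivatives (uM/min) of the TCS species."""
    return _tcs_rhs_arr(state.as_array(), params)


def _basal_rhs_arr(y: np.ndarray, p: BasalTcsParams) -> np.ndarray:
    H, Hp, HL, HpR, HLRp, R, Rp, L, HpL, HpLR, HRp = y
    t = p.tcs
    v_ap = t.k_ap * H                                              # H -> Hp
    v_tb = t.pt_on * Hp * R - t.pt_off * HpR                       # Hp + R <-> HpR
    v_tc = t.pt_cat * HpR                                          # HpR -> H + Rp
    v_eb = t.eff_on * H * L - t.eff_off * HL                       # H + L <-> HL
    v_pb = t.ph_on * HL * Rp - t.ph_off * HLRp                     # HL + Rp <-> HLRp
    v_pc = t.ph_cat * HLRp                                         # HLRp -> HL + R
    v_au = t.k_auto * Rp                                           # Rp -> R
    # basal (crossed) pathways
    v_bap = p.basal_autokinase * t.k_ap * HL                       # HL -> HpL
    v_btb = p.basal_transfer_binding * t.pt_on * HpL * R - t.pt_off * HpLR
    v_btc = p.basal_transfer * t.pt_cat * HpLR                     # HpLR -> HL + Rp
    v_bpb = p.basal_phosphatase_binding * t.ph_on * H * Rp - t.ph_off * HRp
    v_bpc = p.basal_phosphatase * t.ph_cat * HRp                   # HRp -> H + R
    v_heb = p.hp_eff_binding * t.eff_on * Hp * L - p.effective_hp_eff_off * HpL
    return np.array(
        [
            -v_ap - v_eb + v_tc - v_bpb + v_bpc,   # H
            v_ap - v_tb - v_heb,                   # Hp
            v_eb - v_pb + v_pc - v_bap + v_btc,    # HL
            v_tb - v_tc,                           # HpR
            v_pb - v_pc,                           # HLRp
            -v_tb + v_pc + v_au - v_btb + v_bpc,   # R
            v_tc - v_pb - v_au + v_btc - v_bpb,    # Rp
            -v_eb - v_heb,                         # L
            v_bap + v_heb - v_btb,                 # HpL
            v_btb - v_btc,                         # HpLR
            v_bpb - v_bpc,                         # HRp
        ]
    )


def basal_tcs_rhs(state: BasalTcsState, params: BasalTcsParams) -> np.ndarray:
    """Time derivatives (uM/min) of the basal-activity TCS species."""
    return _basal_rhs_arr(state.as_array(), params)


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

_CONSERVED = {
    "cycle": (
        ("S", "Sp", "ES", "ELSp"),
        ("E", "EL", "ES", "ELSp"),
        ("L", "EL", "ELSp"),
    ),
    "tcs": (
        ("R", "Rp", "HpR", "HLRp"),
        ("H", "Hp", "HL", "HpR", "HLRp"),
        ("L", "HL", "HLRp"),
    ),
    "basal": (
        ("R", "Rp", "HpR", "HLRp", "HpLR", "HRp"),
        ("H", "Hp", "HL", "HpR", "HLRp", "HpL", "HpLR", "HRp"),
        ("L", "HL", "HLRp", "HpL", "HpLR"),
    ),
}

_SPECIES = {"cycle": CYCLE_SPECIES, "tcs": TCS_SPECIES, "basal": BASAL_SPECIES}

_STATE_TYPES = {"cycle": CycleState, "tcs": TcsState, "basal": BasalTcsState}


def conservation_totals(state, variant: str) -> tuple[float, float, float]:
    """(total substrate/regulator, total enzyme, total effector) of a state."""
    _require(variant in _CONSERVED, f"unknown variant {variant!r}")
    expected = _STATE_TYPES[variant]
    _require(isinstance(state, expected), f"state {type(state).__name__} does not match variant {variant!r}")
    names = _SPECIES[variant]
    y = state.as_array()
    idx = {n: i for i, n in enumerate(names)}
    return tuple(float(sum(y[idx[n]] for n in group)) for group in _CONSERVED[variant])


def conserved_group_indices(variant: str) -> tuple[tuple[int, ...], ...]:
    """Index tuples of the conserved groups in the variant's species order."""
    names = _SPECIES[variant]
    idx = {n: i for i, n in enumerate(names)}
    return tuple(tuple(idx[n] for n in group) for group in _CONSERVED[variant])


# ---------------------------------------------------------------------------
# (de)serialization of parameter sets
# ---------------------------------------------------------------------------

_UNITS = {
    "first_order": "1/min",
    "second_order": "1/(uM*min)",
    "concentration": "uM",
}

_CYCLE_FIELDS = [f.name for f in dataclasses.fields(CycleParams)]
_TCS_FIELDS = [f.name for f in dataclasses.fields(TcsParams)]
_BASAL_EXTRA = [
    "basal_autokinase",
    "basal_transfer",
    "basal_phosphatase",
    "basal_transfer_binding",
    "basal_phosphatase_binding",
    "hp_eff_binding",
    "hp_eff_off",
]

_SECOND_ORDER = {"kin_on", "pho_on", "eff_on", "pt_on", "ph_on"}
_CONCENTRATION = {"S_T", "E_T", "L_T", "R_T", "H_T"}


def params_to_dict(params) -> dict:
    """Serializable mapping with explicit unit strings."""
    if isinstance(params, BasalTcsParams):
        d = params_to_dict(params.tcs)
        d["variant"] = "basal"
        for name in _BASAL_EXTRA:
            d[name] = getattr(params, name)
        return d
    if isinstance(params, CycleParams):
        variant, names = "cycle", _CYCLE_FIELDS
    elif isinstance(params, TcsParams):
        variant, names = "tcs", _TCS_FIELDS
    else:  # pragma: no cover - defensive
        raise ModelValidationError(f"unsupported parameter type {type(params)}")
    d = {"variant": variant, "units": {}}
    for name in names:
        d[name] = getattr(params, name)
        if name in _SECOND_ORDER:
            d["units"][name] = _UNITS["second_order"]
        elif name in _CONCENTRATION:
            d["units"][name] = _UNITS["concentration"]
        else:
            d["units"][name] = _UNITS["first_order"]
    return d


def params_from_dict(d: Mapping) -> CycleParams | TcsParams | BasalTcsParams:
    """Validate and build a parameter set from a plain mapping.

    Unknown keys are rejected so that typos in configuration files fail
    loudly rather than silently falling back to defaults.
    """
    d = dict(d)
    variant = d.pop("variant", None)
    _require(variant in ("cycle", "tcs", "basal"), f"missing or unknown variant {variant!r}")
    d.pop("units", None)
    if variant == "cycle":
        allowed = set(_CYCLE_FIELDS)
        unknown = set(d) - allowed
        _require(not unknown, f"unknown keys for cycle params: {sorted(unknown)}")
        return CycleParams(**d)
    if variant == "tcs":
        allowed = set(_TCS_FIELDS)
        unknown = set(d) - allowed
        _require(not unknown, f"unknown keys for tcs params: {sorted(unknown)}")
        return TcsParams(**d)
    extra = {k: d.pop(k) for k in list(d) if k in _BASAL_EXTRA}
    unknown = set(d) - set(_TCS_FIELDS)
    _require(not unknown, f"unknown keys for basal params: {sorted(unknown)}")
    return BasalTcsParams(tcs=TcsParams(**d), **extra)


def dump_params(params, path) -> None:
    """Write a parameter set to JSON or YAML depending on the suffix."""
    d = params_to_dict(params)
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
    else:
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def load_params(path) -> CycleParams | TcsParams | BasalTcsParams:
    """Load and validate a parameter set from a JSON or YAML file."""
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            d = json.load(fh)
    return params_from_dict(d)
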