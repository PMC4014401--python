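"""Closed-form reductions of the reciprocally regulated kinase models.

The steady-state behavior of the full mass-action models collapses, in the
limit of substrate excess (R_T >> H_T, or S_T >> E_T), onto a small family of
algebraic forms controlled by the relative effector affinity
``lambda = K_d / (total enzyme)``:

* low affinity (lambda >> 1): free effector ~ total effector; the response is
  graded and described by a quadratic of Batchelor-Goulian form whose
  phosphatase-side constant K1 falls inversely with effector concentration
  (:func:`effective_k1`) and whose transfer-side constant K2 is generated by
  regulator autodephosphorylation (:func:`effective_k2`).
* high affinity (lambda << 1): the effector is stoichiometrically sequestered
  by the enzyme, partitioning it into an effector-bound phosphatase pool of
  size ~L_T and a kinase pool of size ~(total - L_T)
  (:func:`enzyme_partition`).  The response then obeys a Goldbeter-Koshland
  relation with apparent parameters and becomes ultrasensitive near the
  transition point where the two maximal rates balance
  (:func:`transition_point`).

Every approximation here carries a declared validity regime; the ODE oracle
in :mod:`tcskinetics.steady_state` is the arbiter in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

from .model_core import (
    CycleParams,
    TcsParams,
    ModelValidationError,
)

__all__ = [
    "ApparentTransferParams",
    "RegimeReport",
    "RegimeWarning",
    "RegimeError",
    "HIGH_AFFINITY_LAMBDA",
    "LOW_AFFINITY_LAMBDA",
    "apparent_transfer_params",
    "effective_k1",
    "effective_k2",
    "approx_bg_limits",
    "enzyme_partition",
    "transition_point",
    "approx_switch_solution",
    "classify_regime",
]

#: default relative-affinity thresholds delimiting the reduction regimes
HIGH_AFFINITY_LAMBDA = 0.01
LOW_AFFINITY_LAMBDA = 100.0


class RegimeWarning(UserWarning):
    """A reduction was evaluated outside its declared validity regime."""


class RegimeError(ValueError):
    """A reduction was evaluated outside its validity regime in strict mode."""


def _regime_guard(ok: bool, msg: str, strict: bool) -> None:
    if ok:
        return
    if strict:
        raise RegimeError(msg)
    warnings.warn(msg, RegimeWarning, stacklevel=3)


# ---------------------------------------------------------------------------
# apparent phosphotransfer parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ApparentTransferParams:
    """Apparent turnover/Michaelis constant of the combined autokinase +
    phosphotransfer activity.

    Eliminating the autophosphorylation step at steady state merges the
    kinase-pool species (H, Hp, HpR) into a single Michaelis-Menten activity
    acting on free R:

        kcat_app = k_ap * pt_cat / (k_ap + pt_cat)
        Km_app   = Km_t * k_ap / (k_ap + pt_cat)

    The regulatory factor k_ap / (k_ap + pt_cat) multiplies Km_t, so slow
    autophosphorylation (k_ap << pt_cat) deflates the apparent Michaelis
    constant: the transfer step itself may stay first order (Km_t large)
    while the apparent activity still saturates.
    """

    kcat_app: float
    Km_app: float

    def __post_init__(self) -> None:
        if not (self.kcat_app > 0 and self.Km_app > 0):
            raise ModelValidationError("apparent transfer parameters must be > 0")


@dataclass(frozen=True)
class RegimeReport:
    """Diagnostics of the operating regime of a parameter set."""

    label: str
    relative_affinity: float
    saturation_phosphatase: float
    saturation_transfer: float
    ultrasensitivity_condition: bool
    small_regulatory_factor: bool
    transition_point: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def apparent_transfer_params(params: TcsParams) -> ApparentTransferParams:
    """Apparent (kcat, Km) of the autokinase + phosphotransfer activity."""
    if params.k_ap <= 0:
        raise ModelValidationError("apparent transfer parameters need k_ap > 0")
    if params.pt_cat <= 0:
        raise ModelValidationError("apparent transfer parameters need pt_cat > 0")
    f = params.k_ap / (params.k_ap + params.pt_cat)
    return ApparentTransferParams(kcat_app=f * params.pt_cat, Km_app=f * params.Km_t)


def regulatory_factor(params: TcsParams) -> float:
    """k_ap / (k_ap + pt_cat); small values deflate Km_app (graded-to-switch)."""
    return params.k_ap / (params.k_ap + params.pt_cat)


# ---------------------------------------------------------------------------
# low-affinity effective Batchelor-Goulian constants
# ---------------------------------------------------------------------------


def _effective_denominator(L_T: float, p: TcsParams) -> float:
    beta = p.ph_cat * L_T / (p.Km_p * p.K_d)
    D1 = 1.0 + L_T / p.K_d + p.k_ap / p.pt_cat
    return beta * p.H_T + p.k_auto * D1


def effective_k1(L_T: float, params: TcsParams) -> float:
    """Effector-dependent phosphatase-side constant K1 (uM).

        K1(L_T) = k_ap * H_T / (beta * H_T + k_auto * D1)
        beta    = ph_cat * L_T / (Km_p * K_d)
        D1      = 1 + L_T/K_d + k_ap/pt_cat

    K1 sets both the plateau of phosphorylated regulator and (in the plateau
    regime) the total-regulator threshold beyond which the plateau holds.  It
    decreases monotonically with effector and falls off as 1/L_T for large
    L_T; with k_auto = 0 it reduces to k_ap * Km_p * K_d / (ph_cat * L_T).
    The effector-free limit is k_ap * H_T / (k_auto * (1 + k_ap/pt_cat)),
    infinite when the regulator has no autodephosphorylation.
    """
    if L_T < 0:
        raise ModelValidationError("L_T must be >= 0")
    den = _effective_denominator(L_T, params)
    if den == 0.0:
        return math.inf
    return params.k_ap * params.H_T / den


def effective_k2(L_T: float, params: TcsParams) -> float:
    """Transfer-side constant K2 (uM) of the low-affinity quadratic.

        K2(L_T) = k_auto * (k_ap * Km_t / pt_cat) / (beta * H_T + k_auto * D1)

    K2 rounds the corner between the linear rise and the plateau; it vanishes
    with the autodephosphorylation rate, in which case the response is the
    sharp corner min(R_T, K1).  K2 >> K1 is the hyperbolic regime in which
    the half-saturation (~K2) far exceeds the asymptotic level (~K1).
    """
    if L_T < 0:
        raise ModelValidationError("L_T must be >= 0")
    if params.k_auto == 0.0:
        return 0.0
    den = _effective_denominator(L_T, params)
    ktilde = params.k_ap * params.Km_t / params.pt_cat
    return params.k_auto * ktilde / den


# ---------------------------------------------------------------------------
# limiting cases of the Batchelor-Goulian quadratic
# ---------------------------------------------------------------------------


def approx_bg_limits(p, case: str, *, margin: float = 10.0) -> float:
    """Closed-form limits of the BG quadratic root.

    ``case='plateau'`` (K1 >> K2): the response rises ~linearly with R_T and
    saturates at K1, which is simultaneously the threshold; implemented as the
    K2 -> 0 root, min(R_T, K1).  ``case='hyperbolic'`` (K2 >> K1): the
    response is K1 * R_T / (K2 + R_T), a hyperbola whose half-saturation K2
    far exceeds the asymptote K1.

    The selected ordering must hold by at least ``margin`` (default 10x).
    """
    K1, K2, R_T = p.K1, p.K2, p.R_T
    if case == "plateau":
        if not K1 >= margin * K2:
            raise RegimeError(f"plateau case needs K1 >= {margin}*K2 (K1={K1}, K2={K2})")
        return min(R_T, K1)
    if case == "hyperbolic":
        if not K2 >= margin * K1:
            raise RegimeError(f"hyperbolic case needs K2 >= {margin}*K1 (K1={K1}, K2={K2})")
        return K1 * R_T / (K2 + R_T)
    raise ModelValidationError(f"unknown case {case!r}; expected 'plateau' or 'hyperbolic'")


# ---------------------------------------------------------------------------
# high-affinity partition, transition point, switch asymptote
# ---------------------------------------------------------------------------


def _totals(params) -> tuple[float, float]:
    """(total enzyme, total substrate/regulator) for either model variant."""
    if isinstance(params, CycleParams):
        return params.E_T, params.S_T
    if isinstance(params, TcsParams):
        return params.H_T, params.R_T
    raise ModelValidationError(f"unsupported parameter type {type(params).__name__}")


def _rates(params) -> tuple[float, float, float, float]:
    """(kcat_kin, Km_kin, kcat_pho, Km_pho) apparent activities of a variant."""
    if isinstance(params, CycleParams):
        return params.kin_cat, params.Km_K, params.pho_cat, params.Km_P
    app = apparent_transfer_params(params)
    return app.kcat_app, app.Km_app, params.ph_cat, params.Km_p


def enzyme_partition(
    params,
    L_T: float | None = None,
    *,
    lam_threshold: float = HIGH_AFFINITY_LAMBDA,
    strict: bool = False,
) -> tuple[float, float]:
    """(phosphatase_pool, kinase_pool) under tight effector sequestration.

    With a high-affinity effector essentially every effector molecule is
    enzyme-bound, so the effector-bound (phosphatase-active) states sum to
    ~L_T and the remaining enzyme, (total - L_T), carries the kinase
    activity.  Pools sum to the total enzyme by construction.
    """
    E_T, _ = _totals(params)
    if L_T is None:
        L_T = params.L_T
    if not 0 <= L_T < E_T:
        raise RegimeError(f"partition needs 0 <= L_T < total enzyme (L_T={L_T}, total={E_T})")
    _regime_guard(
        params.relative_affinity <= lam_threshold,
        f"enzyme partition assumes high affinity (lambda={params.relative_affinity:.3g} "
        f"> {lam_threshold})",
        strict,
    )
    return L_T, E_T - L_T


def transition_point(
    params,
    *,
    lam_threshold: float = HIGH_AFFINITY_LAMBDA,
    strict: bool = False,
) -> float:
    """Effector concentration L* at the on/off switch of the high-affinity regime.

    Defined by equality of the maximal kinase and phosphatase rates over the
    partitioned pools, kcat_kin * (total - L*) = kcat_pho * L*:

        L* = total / (1 + kcat_pho / kcat_kin)

    where for the TCS the kinase turnover is the apparent one of
    :func:`apparent_transfer_params`.  L* < total enzyme always; it shrinks as
    the phosphatase activity strengthens, and ultrasensitivity is confined to
    effector concentrations below the total enzyme concentration.
    """
    _regime_guard(
        params.relative_affinity <= lam_threshold,
        f"transition point assumes high affinity (lambda={params.relative_affinity:.3g})",
        strict,
    )
    E_T, _ = _totals(params)
    kcat_kin, _, kcat_pho, _ = _rates(params)
    if kcat_kin <= 0:
        raise ModelValidationError("transition point needs a positive kinase turnover")
    return E_T / (1.0 + kcat_pho / kcat_kin)


def approx_switch_solution(
    params,
    L_T: float | None = None,
    *,
    lam_threshold: float = HIGH_AFFINITY_LAMBDA,
    strict: bool = False,
) -> float:
    """Sharp-switch asymptote of the phosphorylated output near L*.

    Zero-order limit of the Goldbeter-Koshland relation keeping only the
    phosphatase Michaelis constant: below the transition (V_kin >= V_pho) the
    output is pinned at the total substrate; above it the residual level is

        Km_pho * V_kin / (V_pho - V_kin)

    clipped to [0, total].  Valid when the ultrasensitivity condition holds
    (apparent Michaelis constants small against the substrate total).
    """
    E_T, S_T = _totals(params)
    if L_T is None:
        L_T = params.L_T
    pho_pool, kin_pool = enzyme_partition(
        params, L_T, lam_threshold=lam_threshold, strict=strict
    )
    kcat_kin, Km_kin, kcat_pho, Km_pho = _rates(params)
    _regime_guard(
        Km_pho <= 0.1 * S_T and Km_kin <= 0.1 * S_T,
        "switch asymptote assumes the ultrasensitivity condition "
        f"(Km_app={Km_kin:.3g}, Km_pho={Km_pho:.3g} vs total={S_T:.3g})",
        strict,
    )
    v_kin = kcat_kin * kin_pool
    v_pho = kcat_pho * pho_pool
    if v_kin >= v_pho:
        return S_T
    return min(S_T, Km_pho * v_kin / (v_pho - v_kin))


def classify_regime(
    params,
    *,
    high_threshold: float = HIGH_AFFINITY_LAMBDA,
    low_threshold: float = LOW_AFFINITY_LAMBDA,
    saturation_threshold: float = 0.1,
) -> RegimeReport:
    """Label the operating regime and populate its diagnostics.

    The relative affinity lambda = K_d / (total enzyme) separates
    ``low_affinity_graded`` (lambda >= low_threshold),
    ``high_affinity_ultrasensitive`` (lambda <= high_threshold) and
    ``intermediate``.  The ultrasensitivity condition additionally requires
    both apparent Michaelis constants to be small against the substrate
    total; the small-regulatory-factor flag records whether slow
    autophosphorylation shifts the transition point to lower effector
    concentrations without spoiling the switch.
    """
    lam = params.relative_affinity
    _, S_T = _totals(params)
    kcat_kin, Km_kin, kcat_pho, Km_pho = _rates(params)
    sat_pho = Km_pho / S_T
    sat_kin = Km_kin / S_T
    if lam >= low_threshold:
        label = "low_affinity_graded"
    elif lam <= high_threshold:
        label = "high_affinity_ultrasensitive"
    else:
        label = "intermediate"
    ultra = sat_pho < saturation_threshold and sat_kin < saturation_threshold
    if isinstance(params, TcsParams):
        small_factor = regulatory_factor(params) < 0.1
    else:
        small_factor = False
    tp = None
    if label == "high_affinity_ultrasensitive":
        tp = transition_point(params, lam_threshold=high_threshold)
    return RegimeReport(
        label=label,
        relative_affinity=lam,
        saturation_phosphatase=sat_pho,
        saturation_transfer=sat_kin,
        ultrasensitivity_condition=ultra,
        small_regulatory_factor=small_factor,
        transition_point=tp,
    )
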