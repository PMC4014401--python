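"""Steady states of the kinase models: stiff integration and algebraic roots.

:func:`integrate_to_steady_state` is the ground-truth oracle: it integrates
the full mass-action system with a stiff-capable adaptive method until the
right-hand side is numerically quiescent, then polishes the state with a
Newton solve constrained to the conservation stoichiometry.  The algebraic
solvers (:func:`solve_bg_quadratic`, :func:`solve_gk` and the regime-specific
reductions) implement the closed-form steady states; each declares a validity
regime and is tested against the oracle inside it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model_core import (
    BASAL_SPECIES,
    CYCLE_SPECIES,
    TCS_SPECIES,
    BasalTcsState,
    CycleParams,
    CycleState,
    ModelValidationError,
    TcsParams,
    TcsState,
    _basal_rhs_arr,
    _cycle_rhs_arr,
    _tcs_rhs_arr,
    conserved_group_indices,
)
from .reduced_models import (
    HIGH_AFFINITY_LAMBDA,
    LOW_AFFINITY_LAMBDA,
    RegimeError,
    _regime_guard,
    apparent_transfer_params,
    effective_k1,
    effective_k2,
    enzyme_partition,
)

__all__ = [
    "BgParams",
    "GkParams",
    "SteadyStateResult",
    "ConvergenceError",
    "integrate_to_steady_state",
    "solve_bg_quadratic",
    "solve_gk",
    "solve_cycle_low_affinity",
    "solve_cycle_high_affinity",
    "solve_tcs_low_affinity",
    "solve_tcs_high_affinity",
]


class ConvergenceError(RuntimeError):
    """Time integration failed to reach a steady state within the horizon."""


@dataclass(frozen=True)
class BgParams:
    """Lumped constants of the Batchelor-Goulian steady-state quadratic.

    ``K1`` is the phosphatase-side constant (sets plateau and, in the plateau
    regime, the threshold), ``K2`` the phosphotransfer-side constant (rounds
    the corner; the half-saturation of the hyperbolic regime), ``R_T`` the
    total response-regulator concentration.  Units are whatever concentration
    or amount unit the data are expressed in, as long as all three agree.
    """

    K1: float
    K2: float
    R_T: float

    def __post_init__(self) -> None:
        if not (self.K1 > 0 and math.isfinite(self.K1)):
            raise ModelValidationError("K1 must be finite and > 0")
        if not self.K2 >= 0:
            raise ModelValidationError("K2 must be >= 0")
        if not self.R_T >= 0:
            raise ModelValidationError("R_T must be >= 0")


@dataclass(frozen=True)
class GkParams:
    """Apparent rates of a Goldbeter-Koshland modification cycle."""

    Vmax_kin: float
    Vmax_pho: float
    Km_kin: float
    Km_pho: float
    S_T: float

    def __post_init__(self) -> None:
        if self.Vmax_kin < 0 or self.Vmax_pho < 0:
            raise ModelValidationError("maximal rates must be >= 0")
        if self.Vmax_kin == 0 and self.Vmax_pho == 0:
            raise ModelValidationError("at least one maximal rate must be > 0")
        if not (self.Km_kin > 0 and self.Km_pho > 0 and self.S_T > 0):
            raise ModelValidationError("Km_kin, Km_pho and S_T must be > 0")


@dataclass(frozen=True)
class SteadyStateResult:
    """A converged steady state plus convergence diagnostics."""

    state: CycleState | TcsState | BasalTcsState
    residual_norm: float
    time_to_converge: float
    method: str

    def to_dict(self) -> dict:
        d = asdict(self)
        d["state"] = asdict(self.state)
        return d


_RHS = {"cycle": _cycle_rhs_arr, "tcs": _tcs_rhs_arr, "basal": _basal_rhs_arr}
_STATE = {"cycle": CycleState, "tcs": TcsState, "basal": BasalTcsState}
_SPECIES = {"cycle": CYCLE_SPECIES, "tcs": TCS_SPECIES, "basal": BASAL_SPECIES}
# species whose RHS rows are swapped for conservation residuals in the polish
_PIVOT = {"cycle": ("S", "E", "L"), "tcs": ("R", "H", "L"), "basal": ("R", "H", "L")}


def _coerce_init(variant: str, params, init):
    cls = _STATE[variant]
    if init is None:
        return cls.initial(params)
    if isinstance(init, cls):
        return init
    return cls.from_array(np.asarray(init, dtype=float))


def _polish(variant: str, params, y: np.ndarray, totals: np.ndarray) -> np.ndarray | None:
    """Newton-polish a near-steady state onto rhs=0 within the conservation class."""
    rhs = _RHS[variant]
    groups = conserved_group_indices(variant)
    names = _SPECIES[variant]
    pivots = [names.index(n) for n in _PIVOT[variant]]

    def fun(z):
        f = rhs(z, params)
        for row, grp, tot in zip(pivots, groups, totals):
            f[row] = z[list(grp)].sum() - tot
        return f

    try:
        sol = root(fun, y, method="hybr", tol=1e-13)
    except Exception:  # pragma: no cover - scipy internal failure
        return None
    z = sol.x
    scale = max(1.0, float(np.max(np.abs(z))))
    if np.any(z < -1e-9 * scale):
        return None
    return np.clip(z, 0.0, None)


def integrate_to_steady_state(
    variant: str,
    params,
    init=None,
    *,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    conv_rtol: float = 1e-10,
    t0: float = 200.0,
    t_max: float = 1e9,
    polish: bool = True,
    method: str = "LSODA",
) -> SteadyStateResult:
    """Integrate a model variant to its steady state.

    The system is integrated over doubling horizons until the RHS infinity
    norm falls below ``conv_rtol * max(1, |state|_inf)`` and the state stops
    moving between horizons (relative change < 1e-8), then Newton-polished
    within the conservation class.  Deterministic for fixed inputs; raises
    :class:`ConvergenceError` if the horizon ``t_max`` model minutes is
    exhausted first (timescales near the graded/saturated corner can be very
    long, see the transient-dynamics discussion in the docs).
    """
    if variant not in _RHS:
        raise ModelValidationError(f"unknown variant {variant!r}")
    state0 = _coerce_init(variant, params, init)
    rhs = _RHS[variant]
    groups = conserved_group_indices(variant)
    y = state0.as_array()
    totals = np.array([y[list(g)].sum() for g in groups])

    t_hi = t0
    t_elapsed = 0.0
    prev = None
    while True:
        sol = solve_ivp(
            lambda t, z: rhs(z, params),
            (0.0, t_hi),
            y,
            method=method,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:  # pragma: no cover - stiff fallback
            sol = solve_ivp(
                lambda t, z: rhs(z, params), (0.0, t_hi), y, method="Radau", rtol=rtol, atol=atol
            )
            if not sol.success:
                raise ConvergenceError(f"integrator failed: {sol.message}")
        y = np.clip(sol.y[:, -1], 0.0, None)
        t_elapsed += t_hi
        # Newton-polish each chunk: jumps to the nearby exact root along the
        # fast directions while the outer loop tracks any slow drift.  A near-
        # degenerate balance (e.g. opposing activities both carried by the
        # same enzyme form) can leave quasi-steady modes with timescales many
        # orders above the kinetic ones, so convergence is declared only when
        # the accepted state itself stops moving between doubled horizons.
        if polish:
            z = _polish(variant, params, y, totals)
            if z is not None:
                res_z = float(np.max(np.abs(rhs(z, params))))
                if res_z < float(np.max(np.abs(rhs(y, params)))):
                    y = z
        scale = max(1.0, float(np.max(np.abs(y))))
        res = float(np.max(np.abs(rhs(y, params))))
        moved = math.inf if prev is None else float(np.max(np.abs(y - prev))) / scale
        if res < conv_rtol * scale and moved < 1e-9:
            break
        prev = y.copy()
        if t_elapsed >= t_max:
            raise ConvergenceError(
                f"no steady state within t={t_max:g} min (residual {res:.3g} uM/min)"
            )
        t_hi = min(2.0 * t_hi, t_max - t_elapsed)
    state = _STATE[variant].from_array(np.clip(y, 0.0, None))
    return SteadyStateResult(state=state, residual_norm=res, time_to_converge=t_elapsed, method="ode")


# ---------------------------------------------------------------------------
# algebraic solvers
# ---------------------------------------------------------------------------


def solve_bg_quadratic(p: BgParams) -> float:
    """Physical root of the Batchelor-Goulian quadratic.

        Rp^2 - (R_T + K1 + K2) Rp + K1 R_T = 0

    computed in the cancellation-free form 2 q / (s + sqrt(s^2 - 4 q)) with
    s = R_T + K1 + K2 and q = K1 R_T.  The smaller root is the unique one in
    [0, min(R_T, K1)]: the output can exceed neither the available regulator
    nor the plateau level.  It is monotone nondecreasing in R_T and
    independent of the total kinase concentration (concentration robustness).
    """
    s = p.R_T + p.K1 + p.K2
    q = p.K1 * p.R_T
    if q == 0.0:
        return 0.0
    disc = s * s - 4.0 * q
    if disc < 0.0:
        if disc < -1e-12 * s * s:  # genuine failure, not round-off
            raise ModelValidationError("BG quadratic has no real root; invalid parameters")
        disc = 0.0
    rp = 2.0 * q / (s + math.sqrt(disc))
    if not 0.0 <= rp <= p.R_T * (1.0 + 1e-12):
        raise ModelValidationError("BG root fell outside [0, R_T]; derivation bug")
    return min(rp, p.R_T)


def solve_gk(p: GkParams) -> float:
    """Modified-substrate fraction of the Goldbeter-Koshland relation.

    Solves  V_kin (1-phi)/(J_kin + 1-phi) = V_pho phi/(J_pho + phi)  with
    J = Km/S_T, taking the admissible root of the quadratic in the stable
    two-term form.  Continuous in all parameters (the linear degenerate case
    V_kin = V_pho is the limit of the quadratic one); phi in [0, 1].
    """
    u1, u2 = p.Vmax_kin, p.Vmax_pho
    j1, j2 = p.Km_kin / p.S_T, p.Km_pho / p.S_T
    if u1 == 0.0:
        return 0.0
    b = u2 - u1 + u2 * j1 + u1 * j2
    c = u1 * j2
    a = u2 - u1
    disc = b * b - 4.0 * a * c
    if disc < 0.0:  # pragma: no cover - cannot occur for valid params
        disc = 0.0
    phi = 2.0 * c / (b + math.sqrt(disc))
    return min(max(phi, 0.0), 1.0)


def solve_cycle_low_affinity(
    params: CycleParams,
    *,
    lam_threshold: float = LOW_AFFINITY_LAMBDA,
    strict: bool = False,
) -> float:
    """Modified fraction of the cycle for a low-affinity effector.

    With free effector ~ L_T, the kinase/phosphatase flux balance gives the
    hyperbolic response

        phi = 1 / (1 + (pho_cat/Km_P) (Km_K/kin_cat) (L_T / K_d))

    graded in the effector (effective Hill coefficient 1); valid for
    lambda = K_d/E_T above ``lam_threshold`` and substrate excess.
    """
    _regime_guard(
        params.relative_affinity >= lam_threshold,
        f"low-affinity reduction outside regime (lambda={params.relative_affinity:.3g} "
        f"< {lam_threshold})",
        strict,
    )
    if params.kin_cat <= 0:
        raise ModelValidationError("low-affinity cycle reduction needs kin_cat > 0")
    x = (params.pho_cat / params.Km_P) * (params.Km_K / params.kin_cat) * (params.L_T / params.K_d)
    return 1.0 / (1.0 + x)


def solve_cycle_high_affinity(
    params: CycleParams,
    *,
    lam_threshold: float = HIGH_AFFINITY_LAMBDA,
    strict: bool = False,
) -> float:
    """Modified fraction of the cycle for a high-affinity effector.

    The effector partitions the enzyme into a phosphatase pool ~L_T and a
    kinase pool ~(E_T - L_T); the response is the Goldbeter-Koshland relation
    over those apparent enzyme concentrations and becomes a zero-order switch
    when both Michaelis constants are saturated.  Requires L_T < E_T (the
    reduction is restricted to low effector concentrations).
    """
    if not params.L_T < params.E_T:
        raise RegimeError("high-affinity reduction requires L_T < E_T")
    pho_pool, kin_pool = enzyme_partition(
        params, params.L_T, lam_threshold=lam_threshold, strict=strict
    )
    return solve_gk(
        GkParams(
            Vmax_kin=params.kin_cat * kin_pool,
            Vmax_pho=params.pho_cat * pho_pool,
            Km_kin=params.Km_K,
            Km_pho=params.Km_P,
            S_T=params.S_T,
        )
    )


def solve_tcs_low_affinity(
    params: TcsParams,
    *,
    lam_threshold: float = LOW_AFFINITY_LAMBDA,
    strict: bool = False,
) -> float:
    """Steady-state Rp (uM) of the TCS for a low-affinity effector.

    The response obeys the Batchelor-Goulian quadratic with the
    effector-dependent constants of :func:`tcskinetics.reduced_models.effective_k1`
    and :func:`~tcskinetics.reduced_models.effective_k2`; valid for
    lambda = K_d/H_T >= ``lam_threshold`` and R_T >> H_T.
    """
    _regime_guard(
        params.relative_affinity >= lam_threshold,
        f"low-affinity reduction outside regime (lambda={params.relative_affinity:.3g})",
        strict,
    )
    _regime_guard(
        params.H_T <= 0.1 * params.R_T,
        f"BG limit assumes R_T >> H_T (H_T/R_T={params.H_T / params.R_T:.3g})",
        strict,
    )
    k1 = effective_k1(params.L_T, params)
    if math.isinf(k1):
        return params.R_T
    k2 = effective_k2(params.L_T, params)
    return solve_bg_quadratic(BgParams(K1=k1, K2=k2, R_T=params.R_T))


def solve_tcs_high_affinity(
    params: TcsParams,
    *,
    lam_threshold: float = HIGH_AFFINITY_LAMBDA,
    strict: bool = False,
) -> float:
    """Steady-state Rp (uM) of the TCS for a high-affinity effector.

    Goldbeter-Koshland relation over the partitioned enzyme pools with the
    apparent phosphotransfer parameters of
    :func:`~tcskinetics.reduced_models.apparent_transfer_params`:

        kcat_app (H_T - L_T) R/(Km_app + R) = ph_cat L_T Rp/(Km_p + Rp)

    with R = R_T - Rp.  Derived without regulator autodephosphorylation;
    requires k_auto = 0 and L_T < H_T.
    """
    if params.k_auto != 0.0:
        raise RegimeError("high-affinity reduction is derived for k_auto = 0")
    if not params.L_T < params.H_T:
        raise RegimeError("high-affinity reduction requires L_T < H_T")
    _regime_guard(
        params.H_T <= 0.1 * params.R_T,
        f"BG limit assumes R_T >> H_T (H_T/R_T={params.H_T / params.R_T:.3g})",
        strict,
    )
    pho_pool, kin_pool = enzyme_partition(
        params, params.L_T, lam_threshold=lam_threshold, strict=strict
    )
    app = apparent_transfer_params(params)
    frac = solve_gk(
        GkParams(
            Vmax_kin=app.kcat_app * kin_pool,
            Vmax_pho=params.ph_cat * pho_pool,
            Km_kin=app.Km_app,
            Km_pho=params.Km_p,
            S_T=params.R_T,
        )
    )
    return frac * params.R_T
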