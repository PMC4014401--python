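"""Stimulus-response curves and their ultrasensitivity/robustness metrics.

The effective Hill coefficient is operationalized through the 10%/90%
dynamic-range points of a monotone dose-response curve,

    n_H = ln(81) / |ln(x90 / x10)|,

the classical definition for which an exact Hill function of exponent n
returns n.  Concentration robustness is quantified on total-protein sweeps by
the plateau level (mean over the top decade of the sweep), the threshold at
which the output first reaches 95% of the plateau, and the maximal log-log
slope beyond the threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import params_to_dict
from .reduced_models import RegimeError
from . import steady_state as ss

__all__ = [
    "SweepSpec",
    "ResponseCurve",
    "HillEstimate",
    "RobustnessReport",
    "build_response_curve",
    "hill_coefficient",
    "robustness_report",
    "stimulus_dependent_robustness",
]


@dataclass(frozen=True)
class SweepSpec:
    """A monotone sweep of one independent variable.

    ``variable`` is the parameter field swept (``L_T``, ``R_T`` or ``S_T``);
    ``grid`` the strictly increasing concentrations (uM, or the dataset's
    amount unit).
    """

    variable: str
    grid: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        if self.grid.ndim != 1 or self.grid.size < 1:
            raise ValueError("sweep grid must be a 1-D array with >= 1 point")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("sweep grid must be strictly increasing")
        if np.any(self.grid < 0):
            raise ValueError("sweep grid must be nonnegative")

    @classmethod
    def log(cls, variable: str, lo: float, hi: float, n: int) -> "SweepSpec":
        return cls(variable, np.geomspace(lo, hi, n))

    @classmethod
    def linear(cls, variable: str, lo: float, hi: float, n: int) -> "SweepSpec":
        return cls(variable, np.linspace(lo, hi, n))


@dataclass(frozen=True)
class ResponseCurve:
    """Steady-state output along a sweep of one variable."""

    variable: str
    grid: np.ndarray
    values: np.ndarray
    solver: str = "ode"
    params: Mapping | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.grid.shape != self.values.shape or self.grid.ndim != 1:
            raise ValueError("grid and values must be 1-D arrays of equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.values < -1e-12):
            raise ValueError("curve values must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.variable: self.grid, "output": self.values})

    def to_csv(self, path) -> None:
        """Write the curve as CSV plus a JSON sidecar with params/solver."""
        self.to_frame().to_csv(path, index=False)
        sidecar = {"variable": self.variable, "solver": self.solver, "params": self.params}
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2, default=float)

    @classmethod
    def from_csv(cls, path) -> "ResponseCurve":
        df = pd.read_csv(path)
        variable = df.columns[0]
        solver, params = "unknown", None
        try:
            with open(str(path) + ".json") as fh:
                sidecar = json.load(fh)
            variable = sidecar.get("variable", variable)
            solver = sidecar.get("solver", solver)
            params = sidecar.get("params")
        except FileNotFoundError:
            pass
        return cls(variable=variable, grid=df.iloc[:, 0].to_numpy(),
                   values=df.iloc[:, 1].to_numpy(), solver=solver, params=params)


@dataclass(frozen=True)
class HillEstimate:
    """Effective Hill coefficient and the dynamic-range landmarks."""

    n_H: float
    x10: float
    x90: float
    direction: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RobustnessReport:
    """Plateau, threshold and residual slope of a total-protein sweep."""

    plateau: float
    threshold: float
    max_slope_beyond: float

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# curve construction
# ---------------------------------------------------------------------------

_SOLVERS: dict[str, Callable] = {
    "cycle_low": lambda p: ss.solve_cycle_low_affinity(p) * p.S_T,
    "cycle_high": lambda p: ss.solve_cycle_high_affinity(p) * p.S_T,
    "tcs_low": ss.solve_tcs_low_affinity,
    "tcs_high": ss.solve_tcs_high_affinity,
}

_ODE_OUTPUT = {"cycle": "Sp", "tcs": "Rp", "basal": "Rp"}


def _ode_solver(variant: str) -> Callable:
    def solve(params):
        res = ss.integrate_to_steady_state(variant, params)
        return getattr(res.state, _ODE_OUTPUT[variant])

    return solve


def build_response_curve(solver, params, sweep: SweepSpec) -> ResponseCurve:
    """Steady-state output (free phosphorylated regulator/substrate, uM) per
    sweep point.

    ``solver`` is a callable ``params -> output``, one of the registered
    algebraic solver names (``cycle_low``, ``cycle_high``, ``tcs_low``,
    ``tcs_high``), or ``"ode:<variant>"`` for the full-model oracle.  Any
    point that fails to converge raises an error naming the point.
    """
    if isinstance(solver, str):
        name = solver
        if solver.startswith("ode:"):
            fn = _ode_solver(solver.split(":", 1)[1])
        elif solver in _SOLVERS:
            fn = _SOLVERS[solver]
        else:
            raise ValueError(f"unknown solver {solver!r}")
    else:
        fn, name = solver, getattr(solver, "__name__", "custom")

    values = np.empty_like(sweep.grid)
    for i, x in enumerate(sweep.grid):
        p = _set_sweep_value(params, sweep.variable, float(x))
        try:
            values[i] = fn(p)
        except ss.ConvergenceError as exc:
            raise ss.ConvergenceError(
                f"sweep point {sweep.variable}={x:g} failed to converge: {exc}"
            ) from exc
    try:
        snapshot = params_to_dict(params)
    except Exception:
        snapshot = None
    return ResponseCurve(variable=sweep.variable, grid=sweep.grid, values=values,
                         solver=name, params=snapshot)


def _set_sweep_value(params, variable: str, x: float):
    from .model_core import BasalTcsParams

    if isinstance(params, BasalTcsParams):
        return params.replace(tcs=params.tcs.replace(**{variable: x}))
    return params.replace(**{variable: x})


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _monotone_direction(values: np.ndarray, tol: float) -> str:
    d = np.diff(values)
    span = float(values.max() - values.min())
    slack = tol * max(span, 1e-300)
    if np.all(d >= -slack):
        return "increasing"
    if np.all(d <= slack):
        return "decreasing"
    raise ValueError("curve is not monotone; refusing to estimate a Hill coefficient")


def hill_coefficient(curve: ResponseCurve, *, monotone_tol: float = 1e-4) -> HillEstimate:
    """Effective Hill coefficient from the 10%/90% dynamic-range points.

    The curve must be monotone with positive dynamic range and at least 8
    points, and the 10%/90% levels must be bracketed by the grid.  Crossing
    points are located by monotone interpolation on the log-x grid;
    decreasing curves are handled through the reciprocal ratio, so n_H is
    always positive.
    """
    x, y = curve.grid, curve.values
    if x.size < 8:
        raise ValueError("need >= 8 grid points for a Hill estimate")
    if np.any(x <= 0):
        raise ValueError("Hill estimate needs a strictly positive grid")
    direction = _monotone_direction(y, monotone_tol)
    span = float(y.max() - y.min())
    if span <= 0:
        raise ValueError("curve has zero dynamic range")
    lo = y.min() + 0.1 * span
    hi = y.min() + 0.9 * span
    ly = y if direction == "increasing" else -y
    lx = np.log(x)
    lo_s, hi_s = (lo, hi) if direction == "increasing" else (-lo, -hi)
    x_lo = float(np.exp(np.interp(lo_s, ly, lx)))
    x_hi = float(np.exp(np.interp(hi_s, ly, lx)))
    if not (x[0] <= min(x_lo, x_hi) and max(x_lo, x_hi) <= x[-1]):  # pragma: no cover
        raise ValueError("dynamic-range landmarks not bracketed by the grid")
    x10, x90 = (x_lo, x_hi)
    ratio = x90 / x10 if direction == "increasing" else x10 / x90
    if ratio == 1.0:
        raise ValueError("degenerate curve: x10 == x90")
    n_h = float(np.log(81.0) / abs(np.log(ratio)))
    return HillEstimate(n_H=n_h, x10=x10, x90=x90, direction=direction)


def half_max_point(curve: ResponseCurve, *, monotone_tol: float = 1e-4) -> float:
    """Sweep value at which the output crosses half of its dynamic range."""
    x, y = curve.grid, curve.values
    direction = _monotone_direction(y, monotone_tol)
    span = float(y.max() - y.min())
    if span <= 0:
        raise ValueError("curve has zero dynamic range")
    mid = y.min() + 0.5 * span
    ly = y if direction == "increasing" else -y
    target = mid if direction == "increasing" else -mid
    return float(np.exp(np.interp(target, ly, np.log(x))))


def robustness_report(
    curve: ResponseCurve,
    *,
    plateau_fraction: float = 0.95,
    slope_tol: float = 0.05,
) -> RobustnessReport:
    """Quantify concentration robustness of a total-protein sweep.

    The plateau is the mean output over the top decade of the sweep; the
    threshold is the first grid crossing of ``plateau_fraction`` x plateau
    (log-interpolated).  The residual log-log slope is evaluated for
    x >= 3 x threshold -- at the threshold itself the slope of any saturating
    curve is ~(1 - plateau_fraction) by construction, so the plateau must be
    certified further out.  A curve whose residual slope exceeds
    ``slope_tol`` there, or whose grid does not reach 3x the threshold, has
    no certified plateau and raises :class:`ValueError`.
    """
    x, y = curve.grid, curve.values
    if x.size < 8:
        raise ValueError("need >= 8 grid points for a robustness report")
    if np.any(x <= 0):
        raise ValueError("robustness report needs a strictly positive grid")
    top = x >= x[-1] / 10.0
    plateau = float(y[top].mean())
    if plateau <= 0:
        raise ValueError("curve plateau is zero; nothing to report")
    target = plateau_fraction * plateau
    above = np.nonzero(y >= target)[0]
    if above.size == 0:  # pragma: no cover - mean construction prevents this
        raise ValueError("curve never reaches the plateau fraction")
    i = int(above[0])
    if i == 0:
        threshold = float(x[0])
    else:
        lx = np.interp(target, [y[i - 1], y[i]], [np.log(x[i - 1]), np.log(x[i])])
        threshold = float(np.exp(lx))
    beyond = x >= 3.0 * threshold
    if beyond.sum() < 2:
        raise ValueError(
            "grid too short beyond the threshold to certify a plateau "
            f"(threshold {threshold:.3g}, grid ends at {x[-1]:.3g})"
        )
    slopes = np.gradient(np.log(np.maximum(y[beyond], 1e-300)), np.log(x[beyond]))
    max_slope = float(np.max(np.abs(slopes)))
    if max_slope > slope_tol:
        raise ValueError(
            f"no plateau: log-log slope beyond 3x threshold is {max_slope:.3g} > {slope_tol}"
        )
    return RobustnessReport(plateau=plateau, threshold=threshold, max_slope_beyond=max_slope)


def stimulus_dependent_robustness(
    params,
    L_T_values: Sequence[float],
    R_T_grid: np.ndarray,
    *,
    solver: str = "bg_effective",
    plateau_fraction: float = 0.95,
    slope_tol: float = 0.05,
) -> dict[float, RobustnessReport]:
    """Robustness reports of total-regulator sweeps at several effector levels.

    In the low-affinity regime the plateau level falls with the effector
    concentration (stimulus-dependent concentration robustness).  The default
    ``bg_effective`` construction evaluates the Batchelor-Goulian quadratic
    with the effector-dependent phosphatase-side constant
    :func:`~tcskinetics.reduced_models.effective_k1` and the effector-free
    transfer-side constant Km_app (the apparent Michaelis constant of the
    combined autokinase + phosphotransfer activity).  In the plateau regime
    (K1 >> K2) the threshold then moves together with the plateau, while in
    the hyperbolic regime (K2 >> K1) the threshold is pinned by the transfer
    constant and only the plateau responds to the stimulus.  Any registered
    curve solver can be substituted via ``solver``.
    """
    from .reduced_models import (
        LOW_AFFINITY_LAMBDA,
        apparent_transfer_params,
        effective_k1,
    )
    from .steady_state import BgParams, solve_bg_quadratic

    if hasattr(params, "relative_affinity") and params.relative_affinity < LOW_AFFINITY_LAMBDA:
        raise RegimeError(
            "stimulus-dependent robustness is a low-affinity-regime analysis "
            f"(lambda={params.relative_affinity:.3g})"
        )
    grid = np.asarray(R_T_grid, dtype=float)
    out: dict[float, RobustnessReport] = {}
    for L in L_T_values:
        if solver == "bg_effective":
            k1 = effective_k1(float(L), params)
            k2 = apparent_transfer_params(params).Km_app
            vals = np.array(
                [solve_bg_quadratic(BgParams(K1=k1, K2=k2, R_T=float(r))) for r in grid]
            )
            curve = ResponseCurve(variable="R_T", grid=grid, values=vals, solver="bg_effective")
        else:
            p = _set_sweep_value(params, "L_T", float(L))
            curve = build_response_curve(solver, p, SweepSpec("R_T", grid))
        out[float(L)] = robustness_report(
            curve, plateau_fraction=plateau_fraction, slope_tol=slope_tol
        )
    return out
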