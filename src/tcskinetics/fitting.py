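"""Least-squares fitting of titration data to the steady-state models.

Two workflows mirror the published experiments:

* :func:`fit_bg` fits the Batchelor-Goulian quadratic root to measurements of
  phosphorylated regulator versus *total regulator* (Phos-tag style
  titrations), estimating the two lumped constants (K1, K2).
* :func:`fit_tcs_autodephos` fits the full TCS model with regulator
  autodephosphorylation to measurements of phosphorylated regulator versus
  *effector* concentration, with an explicit split between fixed and free
  kinetic parameters; every model prediction is a full ODE steady state.

Both optimize in log-parameter space with positivity bounds and a seeded
multi-start protocol, and report per-parameter relative standard errors from
the local quadratic approximation (flat directions show up as standard
errors above 100% rather than being suppressed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model_core import TcsParams
from .steady_state import (
    BgParams,
    ConvergenceError,
    integrate_to_steady_state,
    solve_bg_quadratic,
)

__all__ = [
    "TitrationDataset",
    "FitResult",
    "fit_bg",
    "fit_tcs_autodephos",
    "parameter_recovery_study",
]


@dataclass(frozen=True)
class TitrationDataset:
    """Measured titration points (x, y[, sd]).

    ``x_meaning`` declares the swept variable: ``total_regulator`` for
    phosphorylated-regulator vs total-regulator titrations, ``effector`` for
    phosphorylated-regulator vs effector titrations.  ``truth`` optionally
    carries the generating parameters of synthetic data (for recovery
    scoring); it plays no role in fitting.
    """

    x: np.ndarray
    y: np.ndarray
    x_meaning: str
    sd: np.ndarray | None = None
    units: str = "uM"
    truth: Mapping | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.sd is not None:
            object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if np.any(self.y < 0):
            raise ValueError("y must be nonnegative")
        if self.sd is not None and (self.sd.shape != self.x.shape or np.any(self.sd <= 0)):
            raise ValueError("sd must match x and be strictly positive")
        if self.x_meaning not in ("total_regulator", "effector"):
            raise ValueError("x_meaning must be 'total_regulator' or 'effector'")

    def to_frame(self) -> pd.DataFrame:
        d = {"x": self.x, "y": self.y}
        if self.sd is not None:
            d["sd"] = self.sd
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        """CSV of the points plus a JSON sidecar with meaning/units/truth."""
        self.to_frame().to_csv(path, index=False)
        with open(str(path) + ".json", "w") as fh:
            json.dump(
                {"x_meaning": self.x_meaning, "units": self.units,
                 "truth": dict(self.truth) if self.truth else None},
                fh, indent=2, default=float,
            )

    @classmethod
    def from_csv(cls, path) -> "TitrationDataset":
        df = pd.read_csv(path)
        meta = {"x_meaning": "total_regulator", "units": "uM", "truth": None}
        try:
            with open(str(path) + ".json") as fh:
                meta.update(json.load(fh))
        except FileNotFoundError:
            pass
        return cls(
            x=df["x"].to_numpy(), y=df["y"].to_numpy(),
            sd=df["sd"].to_numpy() if "sd" in df else None,
            x_meaning=meta["x_meaning"], units=meta["units"], truth=meta["truth"],
        )


@dataclass(frozen=True)
class FitResult:
    """Estimates, diagnostics and provenance of one least-squares fit."""

    estimates: dict[str, float]
    fixed: dict[str, float]
    rss: float
    converged: bool
    rel_std_err: dict[str, float]
    n_starts: int
    objective_history: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return asdict(self)


def _weights(dataset: TitrationDataset) -> np.ndarray:
    if dataset.sd is not None:
        return 1.0 / dataset.sd
    return np.ones_like(dataset.y)


def _rel_std_err(res, names: Sequence[str], theta: np.ndarray) -> dict[str, float]:
    """Relative standard errors from the Gauss-Newton curvature in log space.

    In log-parameter space the covariance diagonal is directly the squared
    relative error; singular directions are reported as infinite.
    """
    m, n = res.jac.shape
    dof = max(m - n, 1)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        rel = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        rel = np.full(n, np.inf)
    return {name: float(r) for name, r in zip(names, rel)}


def _multistart_ls(
    residual: Callable[[np.ndarray], np.ndarray],
    theta0: np.ndarray,
    *,
    n_starts: int,
    seed: int,
    spread: float = 1.0,
    max_nfev: int | None = None,
) -> tuple:
    """Seeded multi-start least squares in log space; returns the best result
    and the (sorted, decreasing) objective history of accepted starts."""
    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(theta0 + rng.normal(0.0, spread, size=theta0.size))
    best = None
    history: list[float] = []
    for s in starts:
        try:
            res = least_squares(residual, s, method="trf", max_nfev=max_nfev)
        except (ConvergenceError, FloatingPointError, ValueError):
            continue
        if best is None or res.cost < best.cost:
            best = res
            history.append(float(2.0 * res.cost))
    if best is None:
        raise ConvergenceError("all optimizer starts failed")
    return best, tuple(history)


# ---------------------------------------------------------------------------
# Batchelor-Goulian quadratic fit (total-regulator titrations)
# ---------------------------------------------------------------------------


def fit_bg(
    dataset: TitrationDataset,
    init: BgParams | tuple[float, float] | None = None,
    *,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Fit the two lumped constants (K1, K2) of the BG quadratic.

    Each prediction is the physical quadratic root at the data point's total
    regulator.  Optimization is over (log K1, log K2) with a seeded
    multi-start around the initial guess; unweighted least squares unless the
    dataset carries standard deviations (then inverse-variance weighting).
    The default initial guess takes K1 from the top of the curve and K2 from
    its half-rise.
    """
    if dataset.x_meaning != "total_regulator":
        raise ValueError("fit_bg expects a total-regulator titration")
    x, y = dataset.x, dataset.y
    w = _weights(dataset)
    if init is None:
        k1_0 = max(float(y.max()), 1e-12)
        k2_0 = max(float(np.interp(0.5 * y.max(), y, x)), 1e-12)
        init = (k1_0, k2_0)
    elif isinstance(init, BgParams):
        init = (init.K1, init.K2)
    theta0 = np.log(np.asarray(init, dtype=float))

    def residual(theta: np.ndarray) -> np.ndarray:
        k1, k2 = np.exp(theta)
        pred = np.array([solve_bg_quadratic(BgParams(K1=k1, K2=k2, R_T=xi)) for xi in x])
        return w * (pred - y)

    best, history = _multistart_ls(residual, theta0, n_starts=n_starts, seed=seed)
    k1, k2 = np.exp(best.x)
    return FitResult(
        estimates={"K1": float(k1), "K2": float(k2)},
        fixed={},
        rss=float(2.0 * best.cost),
        converged=bool(best.success),
        rel_std_err=_rel_std_err(best, ["K1", "K2"], best.x),
        n_starts=n_starts,
        objective_history=history,
    )


# ---------------------------------------------------------------------------
# full-model fit with autodephosphorylation (effector titrations)
# ---------------------------------------------------------------------------

_TCS_FREE_OK = ("Km_t", "Km_p", "pt_cat", "ph_cat", "k_ap", "k_auto", "eff_off", "eff_on")


def _apply_free(params: TcsParams, names: Sequence[str], values: np.ndarray) -> TcsParams:
    kw = dict(zip(names, values))
    km_t = kw.pop("Km_t", None)
    km_p = kw.pop("Km_p", None)
    p = params.replace(**kw) if kw else params
    if km_t is not None or km_p is not None:
        p = p.with_km(Km_t=km_t, Km_p=km_p)
    return p


def fit_tcs_autodephos(
    dataset: TitrationDataset,
    params_init: TcsParams,
    free: Sequence[str] = ("Km_t", "Km_p", "pt_cat", "ph_cat"),
    *,
    n_starts: int = 3,
    seed: int = 0,
    spread: float = 0.5,
    max_nfev: int = 60,
) -> FitResult:
    """Fit free kinetic parameters of the TCS model to an effector titration.

    ``params_init`` provides both the initial guess for the free parameters
    and the values of all fixed ones (including ``k_auto``, typically fixed
    at ln 2 / half-life of the phosphorylated regulator).  Every residual
    evaluation integrates the full mass-action model to steady state at each
    effector concentration; the fit is performed on the logs of the free
    parameters, with Michaelis constants adjusted through the on-rates.
    """
    if dataset.x_meaning != "effector":
        raise ValueError("fit_tcs_autodephos expects an effector titration")
    unknown = set(free) - set(_TCS_FREE_OK)
    if unknown:
        raise ValueError(f"unsupported free parameters: {sorted(unknown)}")
    x, y = dataset.x, dataset.y
    w = _weights(dataset)
    names = list(free)
    theta0 = np.log(
        np.array([getattr(params_init, n) if hasattr(params_init, n) else None for n in names],
                 dtype=float)
    )

    def predict(p: TcsParams) -> np.ndarray:
        out = np.empty_like(x)
        for i, L in enumerate(x):
            res = integrate_to_steady_state("tcs", p.replace(L_T=float(L)))
            out[i] = res.state.Rp
        return out

    def residual(theta: np.ndarray) -> np.ndarray:
        p = _apply_free(params_init, names, np.exp(theta))
        return w * (predict(p) - y)

    best, history = _multistart_ls(
        residual, theta0, n_starts=n_starts, seed=seed, spread=spread, max_nfev=max_nfev
    )
    values = np.exp(best.x)
    fitted = _apply_free(params_init, names, values)
    fixed = {
        f: getattr(fitted, f)
        for f in ("k_ap", "pt_off", "pt_cat", "ph_off", "ph_cat", "eff_on", "eff_off",
                  "k_auto", "R_T", "H_T")
        if f not in names
    }
    return FitResult(
        estimates={n: float(v) for n, v in zip(names, values)},
        fixed=fixed,
        rss=float(2.0 * best.cost),
        converged=bool(best.success),
        rel_std_err=_rel_std_err(best, names, best.x),
        n_starts=n_starts,
        objective_history=history,
    )


# ---------------------------------------------------------------------------
# recovery harness
# ---------------------------------------------------------------------------


def parameter_recovery_study(
    generator: Callable[[int], tuple[TitrationDataset, Mapping[str, float]]],
    fitter: Callable[[TitrationDataset], FitResult],
    n_replicates: int,
    seed: int,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Monte-Carlo recovery study over seeded synthetic replicates.

    ``generator(replicate_seed)`` must return a dataset and its ground-truth
    parameter mapping; ``fitter`` maps a dataset to a :class:`FitResult`.
    Returns the per-replicate table (one row per replicate and parameter,
    with the relative error) and a per-parameter summary with median absolute
    relative error, bias and relative RMSE.  Failed fits are counted in the
    summary (``n_failed``), not fatal.  Deterministic for a fixed seed.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    rows = []
    n_failed = 0
    for r, s in enumerate(child_seeds):
        ds, truth = generator(int(s) % (2**31 - 1))
        try:
            fit = fitter(ds)
        except (ConvergenceError, ValueError):
            n_failed += 1
            continue
        for name, est in fit.estimates.items():
            if name not in truth:
                continue
            rel = (est - truth[name]) / truth[name]
            rows.append({"replicate": r, "parameter": name, "estimate": est,
                         "truth": truth[name], "rel_error": rel})
    table = pd.DataFrame(rows)
    summary: dict[str, dict[str, float]] = {}
    if not table.empty:
        for name, grp in table.groupby("parameter"):
            e = grp["rel_error"].to_numpy()
            summary[name] = {
                "median_abs_rel_error": float(np.median(np.abs(e))),
                "bias": float(np.mean(e)),
                "rel_rmse": float(np.sqrt(np.mean(e**2))),
                "n": int(e.size),
            }
    summary["_meta"] = {"n_replicates": n_replicates, "n_failed": n_failed}
    return table, summary
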