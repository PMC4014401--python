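"""Synthetic titration datasets emulating the published measurement designs.

Two dataset shapes are emulated: phosphorylated-regulator versus
*total-regulator* titrations (Phos-tag quantification style, one preset with
plateau ~ threshold and one hyperbolic preset whose half-saturation far
exceeds the plateau) and phosphorylated-regulator versus *effector*
titrations (graded low-affinity, ultrasensitive high-affinity, and an
NRI-like high-affinity system whose autodephosphorylation damps the switch).

The noise model is multiplicative Gaussian with a fixed coefficient of
variation, truncated at a floor of zero -- gel/Phos-tag quantifications have
roughly proportional errors.  Every dataset derives its own independent
random stream from an explicit seed; there is no global state.  Generated
datasets carry their ground-truth parameters alongside for recovery scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fitting import TitrationDataset
from .model_core import TcsParams, params_to_dict
from .response_metrics import SweepSpec, build_response_curve
from .steady_state import BgParams, solve_bg_quadratic

__all__ = [
    "NoiseModel",
    "RegimePreset",
    "generate_titration",
    "preset_catalog",
    "get_preset",
]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian measurement noise, y -> y (1 + cv N(0,1)).

    Samples are truncated below at ``floor`` (uM).  A seed is mandatory
    whenever cv > 0 so that datasets are reproducible by construction.
    """

    cv: float = 0.05
    floor: float = 0.0
    seed: int | None = None
    kind: str = "additive_gaussian_cv"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.kind != "additive_gaussian_cv":
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.cv > 0 and self.seed is None:
            raise ValueError("a seed is required for nonzero cv")

    def apply(self, y: np.ndarray) -> np.ndarray:
        if self.cv == 0:
            return np.asarray(y, dtype=float).copy()
        rng = np.random.default_rng(self.seed)
        noisy = y * (1.0 + self.cv * rng.standard_normal(y.shape))
        return np.maximum(noisy, self.floor)


@dataclass(frozen=True)
class RegimePreset:
    """A named parameter regime with its canonical sweep and solver."""

    name: str
    params: BgParams | TcsParams
    sweep: SweepSpec
    solver: str
    expected_label: str | None
    x_meaning: str
    units: str = "uM"
    description: str = ""


def _bg_predict(p: BgParams, grid: np.ndarray) -> np.ndarray:
    return np.array([solve_bg_quadratic(BgParams(K1=p.K1, K2=p.K2, R_T=float(x))) for x in grid])


def generate_titration(
    preset_or_params,
    sweep: SweepSpec | None = None,
    noise: NoiseModel = NoiseModel(cv=0.0),
    *,
    solver: str | None = None,
    x_meaning: str | None = None,
    units: str = "uM",
) -> TitrationDataset:
    """Noisy titration dataset from a preset or explicit parameters.

    Predictions come from the preset's solver (the BG quadratic for
    total-regulator presets, the full ODE oracle for effector presets);
    noise is applied by the :class:`NoiseModel`.  The returned dataset
    stores the ground-truth parameters and seed in ``truth``.
    """
    if isinstance(preset_or_params, RegimePreset):
        preset = preset_or_params
        params = preset.params
        sweep = sweep or preset.sweep
        solver = solver or preset.solver
        x_meaning = x_meaning or preset.x_meaning
        units = preset.units
    else:
        params = preset_or_params
        if sweep is None:
            raise ValueError("an explicit sweep is required without a preset")
        if x_meaning is None:
            x_meaning = "total_regulator" if sweep.variable in ("R_T", "S_T") else "effector"
        solver = solver or "ode:tcs"

    if isinstance(params, BgParams):
        y = _bg_predict(params, sweep.grid)
        truth = {"K1": params.K1, "K2": params.K2}
    else:
        curve = build_response_curve(solver, params, sweep)
        y = curve.values
        truth = params_to_dict(params)
        truth.pop("units", None)
        truth["Km_t"] = params.Km_t
        truth["Km_p"] = params.Km_p
    truth["seed"] = noise.seed
    truth["cv"] = noise.cv
    return TitrationDataset(
        x=sweep.grid, y=noise.apply(y), x_meaning=x_meaning, units=units, truth=truth
    )


# ---------------------------------------------------------------------------
# preset catalog
# ---------------------------------------------------------------------------

_LN2_OVER_5 = math.log(2.0) / 5.0  # autodephosphorylation with 5-minute half-life


def preset_catalog() -> list[RegimePreset]:
    """The five study regimes, constructed to satisfy their regime inequalities.

    * ``plateau_robust`` -- BG constants with K1 >> K2 (plateau ~ threshold,
      a sharp corner at the K1 threshold, Phos-tag style).
    * ``hyperbolic_robust`` -- K2 >> K1: hyperbolic rise whose half-saturation
      is ~25x the asymptotic level (NRI-P style).
    * ``graded_low_affinity`` -- TCS with lambda = K_d/H_T = 1000 and
      autodephosphorylation; graded (n_H ~ 1) effector response.
    * ``ultrasensitive_high_affinity`` -- TCS with lambda = 1e-3 and both
      apparent Michaelis constants at ~1-2% of R_T; zero-order switch.
    * ``nri_like_autodephos`` -- high-affinity TCS damped by
      autodephosphorylation with a 5-minute half-life.
    """
    presets = [
        RegimePreset(
            name="plateau_robust",
            params=BgParams(K1=6.0, K2=0.06, R_T=1.0),
            sweep=SweepSpec.log("R_T", 0.3, 100.0, 12),
            solver="bg",
            expected_label=None,
            x_meaning="total_regulator",
            units="pmol",
            description="plateau regime: threshold ~ plateau ~ K1",
        ),
        RegimePreset(
            name="hyperbolic_robust",
            params=BgParams(K1=6.0, K2=150.0, R_T=1.0),
            sweep=SweepSpec.log("R_T", 2.0, 3000.0, 12),
            solver="bg",
            expected_label=None,
            x_meaning="total_regulator",
            units="pmol",
            description="hyperbolic regime: half-saturation K2 >> plateau K1",
        ),
        RegimePreset(
            name="graded_low_affinity",
            params=TcsParams(
                k_ap=1.0,
                pt_on=0.05, pt_off=1.0, pt_cat=1.0,      # Km_t = 40 uM (transfer first order)
                ph_on=10.0, ph_off=1.0, ph_cat=10.0,     # Km_p = 1.1 uM
                eff_on=0.2, eff_off=10.0,                # K_d = 50 uM, lambda = 1000
                R_T=1.0, H_T=0.05, L_T=0.0,
                k_auto=0.1,
            ),
            sweep=SweepSpec.log("L_T", 1.0, 20000.0, 15),
            solver="ode:tcs",
            expected_label="low_affinity_graded",
            x_meaning="effector",
            description="low-affinity effector: graded hyperbolic response, n_H ~ 1",
        ),
        RegimePreset(
            name="ultrasensitive_high_affinity",
            params=TcsParams(
                k_ap=0.5,
                pt_on=55.0, pt_off=1.0, pt_cat=10.0,     # Km_t = 0.2 uM, Km_app = 0.0095 uM
                ph_on=20.0, ph_off=1.0, ph_cat=1.0,      # Km_p = 0.1 uM = 1% of R_T
                eff_on=100.0, eff_off=0.01,              # K_d = 1e-4 uM, lambda = 1e-3
                R_T=10.0, H_T=0.1, L_T=0.0,
                k_auto=0.0,
            ),
            sweep=SweepSpec.log("L_T", 1e-3, 0.095, 15),
            solver="ode:tcs",
            expected_label="high_affinity_ultrasensitive",
            x_meaning="effector",
            description="high-affinity effector, saturated activities: zero-order switch",
        ),
        RegimePreset(
            name="nri_like_autodephos",
            params=TcsParams(
                k_ap=2.0,
                pt_on=5.0, pt_off=1.0, pt_cat=4.0,       # Km_t = 1 uM
                ph_on=6.0, ph_off=1.0, ph_cat=2.0,       # Km_p = 0.5 uM
                eff_on=10.0, eff_off=0.025,              # K_d = 2.5e-3 uM, lambda = 0.01
                R_T=25.0, H_T=0.25, L_T=0.0,
                k_auto=_LN2_OVER_5,                      # 5-minute half-life of Rp
            ),
            sweep=SweepSpec.log("L_T", 5e-3, 0.24, 12),
            solver="ode:tcs",
            expected_label="high_affinity_ultrasensitive",
            x_meaning="effector",
            description="high-affinity system damped by RR autodephosphorylation",
        ),
    ]
    return presets


def get_preset(name: str) -> RegimePreset:
    for p in preset_catalog():
        if p.name == name:
            return p
    raise KeyError(f"unknown preset {name!r}")
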