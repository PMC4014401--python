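# Methods

This note records the models, derivations, parameter choices and numerical
decisions behind `tcskinetics`, in the package's own words.  Units are µM and
minutes throughout the concentration basis; second-order rate constants are
µM⁻¹min⁻¹.  Amounts (pmol) are used for the two-compartment bookkeeping and
for dataset presets quoted in pmol.

## Models

**Covalent modification cycle (`cycle`).**  A bifunctional converter enzyme E
phosphorylates substrate S through a Michaelis complex (E + S ⇌ ES → E + Sp,
rates `kin_on/kin_off/kin_cat`); the effector-bound form EL carries the
phosphatase activity (EL + Sp ⇌ ELSp → EL + S, `pho_*`); the effector binds
the free enzyme only (E + L ⇌ EL, `eff_*`).  Free E has no phosphatase
activity and EL no kinase activity, so effector binding reciprocally switches
the enzyme between its two activities.  Conservation: S-group, E-group,
L-group sums are invariant.

**Two-component system (`tcs`).**  Free HK autophosphorylates (H → Hp, rate
`k_ap`, ATP lumped as constant), transfers through a complex
(Hp + R ⇌ HpR → H + Rp, `pt_*`), the effector binds free H (H + L ⇌ HL,
`eff_*`), and the effector-bound form is the phosphatase
(HL + Rp ⇌ HLRp → HL + R, `ph_*`).  An optional first-order
autodephosphorylation Rp → R (`k_auto`) models the intrinsic phosphatase
activity of response regulators; `k_auto = ln 2 / t_half` (a 5-minute
half-life gives 0.1386 min⁻¹).

**Basal extension (`basal`).**  Adds the crossed pathways with scale factors:
HL → HpL (autokinase on the bound form, factor `basal_autokinase` = φ_a),
HpL + R ⇌ HpLR → HL + Rp (transfer from the bound phospho-form, catalytic
factor `basal_transfer`, association scale `basal_transfer_binding`),
H + Rp ⇌ HRp → H + R (phosphatase on the free form, `basal_phosphatase`,
`basal_phosphatase_binding`), and effector binding to Hp
(`hp_eff_binding` = γ, dissociation rate `hp_eff_off`).  To prevent a net
steady cycle flux around the H/Hp/HL/HpL binding–phosphorylation square, the
Kolmogorov rate-product condition fixes `hp_eff_off = γ·eff_off/φ_a`,
equivalently K_d(Hp) = K_d/φ_a: weaker basal autokinase on HL goes together
with proportionally weaker effector binding to the phosphorylated HK.
`consistent_hp_eff_off` derives this value; constructing inconsistent
parameters emits a warning.

State vectors always carry every species; the three conservation sums are
test invariants (checked to 1e-12 over 1000 random states per variant), not
eliminations.

## Steady states

`integrate_to_steady_state` is the oracle: LSODA (Radau fallback) over
doubling time horizons, with a Newton polish after each chunk in which three
RHS rows are replaced by the conservation residuals.  Convergence is declared
only when the accepted state stops moving between doubled horizons
(relative change < 1e-9) *and* the RHS infinity norm is below
`conv_rtol·max(1, |state|)` (default 1e-10).  The state-movement criterion
matters: when an unregulated phosphatase route balances the autokinase — both
fluxes proportional to free HK — the slowest eigenvalue can fall to
~1e-9 min⁻¹ and residual-only stopping freezes initial-condition memory at
the 0.5% level.  In that degenerate corner the equilibrium position along the
slow direction sits below float64 resolution of the RHS; curve-level metrics
built on such regimes are accurate to a few tenths of a percent, not machine
precision.  Default initial condition: all protein free and unmodified,
effector free.

**Batchelor–Goulian quadratic.**  In the substrate-excess limit
(R_T ≫ H_T, complexes negligible in the R-conservation) the steady state of
the low-affinity TCS obeys

    Rp² − (R_T + K1 + K2)·Rp + K1·R_T = 0,

computed in the cancellation-free form `2q/(s + √(s²−4q))`; the smaller root
is the unique physical one in [0, min(R_T, K1)].  The derivation uses three
exact steady-state relations: HL = H·L/K_d, the complex quasi-equilibria
HpR = Hp·R/Km_t and HLRp = HL·Rp/Km_p, and the flux chain
k_ap·H = pt_cat·HpR = ph_cat·HLRp + k_auto·Rp.  With `k_auto = 0` the free-HK
concentration cancels from the autokinase/phosphatase balance, which pins

    K1 = k_ap·Km_p·K_d / (ph_cat·L_T)    and    K2 = 0:

the response is the *sharp corner* min(R_T, K1), and is exactly independent
of H_T (absolute concentration robustness) — confirmed against the ODE to
<0.1% including the corner point.  Regulator autodephosphorylation lifts the
degeneracy; eliminating H from the enzyme conservation
H = H_T·R/(D1·R + K̃), with K̃ = k_ap·Km_t/pt_cat and
D1 = 1 + L_T/K_d + k_ap/pt_cat, yields

    K1 = k_ap·H_T / (β·H_T + k_auto·D1),      β = ph_cat·L_T/(Km_p·K_d),
    K2 = k_auto·K̃ / (β·H_T + k_auto·D1),

verified against the full ODE to ~0.1% across (K1, K2, R_T) decades.  The
plateau regime (K1 ≫ K2) rises linearly to a threshold equal to the plateau
K1; the hyperbolic regime (K2 ≫ K1) has half-saturation K2 far above the
asymptote K1 — in this model family the hyperbolic regime *requires*
autodephosphorylation.  The reduction drops the HLRp term from the enzyme
conservation; its validity needs (L_T/K_d)(Rp/Km_p) ≪ D1, i.e. an
unsaturated phosphatase complex (or `k_auto = 0`, where the corner result is
exact regardless).

Because K1 and K2 share the common denominator, effector changes move
plateau and threshold together in the exact reduction.  The classical
stimulus-robustness dichotomy (threshold pinned in the hyperbolic regime,
co-moving in the plateau regime) is recovered by
`stimulus_dependent_robustness`'s default `bg_effective` construction, which
holds the transfer-side constant at its effector-free value — identified
with Km_app, the apparent transfer Michaelis constant — while K1 varies with
the stimulus.

**Goldbeter–Koshland relation.**  `solve_gk` returns the admissible root of
V_kin(1−φ)/(J_kin+1−φ) = V_pho·φ/(J_pho+φ) in the stable two-term form,
continuous through the V_kin = V_pho degeneracy; it is cross-checked against
a bracketing bisection oracle.

**High-affinity reductions.**  Tight effector sequestration partitions the
enzyme into a phosphatase pool ≈ L_T and a kinase pool ≈ total − L_T
(`enzyme_partition`).  For the cycle the GK relation over those pools is
exact up to the partition itself.  For the TCS, eliminating the
autophosphorylation step merges the kinase-pool species into one apparent
Michaelis-Menten activity with `kcat_app = k_ap·pt_cat/(k_ap+pt_cat)` and
`Km_app = k_ap·Km_t/(k_ap+pt_cat)`; the regulatory factor k_ap/(k_ap+pt_cat)
multiplies Km_t, so slow autophosphorylation lets the transfer step stay
first order (Km_t ≫ R_T) without spoiling the switch — at the price of a
transition point `L* = H_T/(1+ph_cat/kcat_app)` shifted to lower effector
concentrations.  The sharp-switch asymptote keeps only the phosphatase
Michaelis constant: Rp = R_T below L*, `Km_p·V_kin/(V_pho−V_kin)` above,
clipped to [0, R_T].

**Regime thresholds and validity windows.**  Defaults: high affinity
λ ≤ 0.01, low affinity λ ≥ 100 (overridable); outside them the solvers warn
rather than silently extrapolate, or raise with `strict=True`.  Limiting-case
formulas require a 10× ordering margin.  One caveat discovered during
validation: in the saturated cycle the free-effector level is amplified by
substrate saturation (L_free ≈ λ·L_T·(1+S/Km_K)/pool), so the operative
high-affinity condition is λ·S_T/Km_K ≪ 1, not λ ≤ 0.01 alone; the
oracle-equivalence grids sample λ ∈ [2e-5, 2e-4] at Km/S_T ∈ [0.01, 0.02],
where the GK reduction meets a 3% absolute tolerance including the transition
cliff.  Pointwise comparison *at* a zero-order cliff is ill-conditioned (the
slope ~1/J amplifies permille-level transition-position corrections); the
transition location itself is checked separately at the 5% level, and the
sharp-switch asymptote is compared outside a ±10% window around L*.

## Two-compartment bookkeeping

For transmembrane sensing, catalysis is cytosolic while the effector is
sensed in the periplasm or outside.  Written in average molecule numbers the
mass balances are volume-free; in concentrations, a periplasmic effector at
concentration c acts like a cytosolic effector at c/α with
α = V_cyt/V_ext, so `two_compartment_rescale` maps `eff_on → α·eff_on`
(K_d → K_d/α) and `L_T → L_T/α` and the high-affinity condition becomes
K_d ≪ α·H_T: periplasmic sensing (α = 1.5–4 for a periplasm occupying
40–20% of the cell) favors ultrasensitivity, dilute extracellular sensing
(α ≪ 1) suppresses it.

## Response metrics

The effective Hill coefficient uses the 10%/90% points of the observed
dynamic range, n_H = ln 81/|ln(x90/x10)|, located by monotone interpolation
on the log-x grid; decreasing curves use the reciprocal ratio.  Calibration:
exact Hill functions with exponents 0.5–8 are recovered within 2% when the
grid spans the asymptotes.  Non-monotone curves are an error (tolerance 1e-4
of the span absorbs steady-state solver noise), never silently truncated.

Robustness reports on total-protein sweeps define the plateau as the mean
over the top decade of the sweep and the threshold as the first 95% crossing.
At the 95% point any saturating curve still has log-log slope ≈ 0.05, so the
plateau is certified by the residual slope at x ≥ 3× threshold (must be
< 0.05; BG curves achieve < 0.02).  Under the 95% rule, "threshold ≈ plateau"
requires K2/K1 ≲ 0.013 (threshold = 0.95·K1 + 19·K2 analytically), which sets
the plateau preset's K2/K1 = 0.01.

## Fitting

`fit_bg` estimates (K1, K2) from total-regulator titrations by least squares
on the quadratic root; `fit_tcs_autodephos` fits a declared free subset of
TCS parameters (Michaelis constants via the on-rates, catalytic rates,
optionally k_ap/k_auto) to effector titrations with every prediction a full
ODE steady state.  Both optimize log-parameters (positivity by construction)
with a seeded multi-start protocol (5 starts for the BG fit, 3 for the ODE
fit), inverse-variance weighting when measurement SDs are given, and report
per-parameter relative standard errors from the Gauss-Newton curvature in
log space — near-flat directions appear as standard errors above 100% rather
than being suppressed.  `parameter_recovery_study` runs seeded Monte-Carlo
replicates and summarizes median absolute relative error, bias and relative
RMSE per parameter; failed fits are counted, not fatal.

## Synthetic data

The generator emulates the two published measurement designs: RR‑P versus
total RR (Phos-tag-style, 12-point log grids) and RR‑P versus effector.
Noise is multiplicative Gaussian with a fixed coefficient of variation
(default 5%), truncated at zero — gel and Phos-tag quantifications have
roughly proportional error; the model is a deliberate simplification
(no baseline noise floor, no lognormal skew) and is swappable.  Each dataset
derives an independent stream from an explicit seed and stores its
ground-truth parameters alongside.  What passing recovery tests show is that
the *estimation machinery* inverts data generated under the model's own
assumptions; they say nothing about model misspecification, correlated
errors, or calibration drift in real gels.

Preset regimes (chosen once to satisfy the stated regime inequalities, with
in-vitro-plausible magnitudes):

* `plateau_robust` — BG constants K1 = 6, K2 = 0.06 pmol, R_T swept
  0.3–100 pmol: linear rise, threshold ≈ plateau.
* `hyperbolic_robust` — K1 = 6, K2 = 150 pmol, R_T swept 2–3000 pmol:
  half-saturation ≈ 25× the plateau.
* `graded_low_affinity` — λ = 1000 (K_d = 50 µM, H_T = 0.05 µM), first-order
  transfer (Km_t = 40 µM), k_auto = 0.1 min⁻¹; the effector response is an
  exact hyperbola (measured n_H = 1.02).  Without autodephosphorylation the
  low-affinity response is the corner min(R_T, K1(L)), whose 10–90 steepness
  is n_H ≈ 2, not a hyperbola — the graded exemplar therefore carries k_auto,
  consistent with the minutes-scale RR‑P half-lives of such systems.
* `ultrasensitive_high_affinity` — λ = 1e-3, Km_p = 1% of R_T,
  Km_app = 0.1% of R_T via k_ap = 0.5 ≪ pt_cat = 10 min⁻¹; measured
  n_H ≈ 16 with the ODE half-max within 1.2% of L*.  The small k_ap/pt_cat
  ratio is also what keeps the basal autokinase/transfer perturbation mild:
  the phospho-leak of the effector-bound pool scales with k_ap relative to
  the transfer return flux.
* `nri_like_autodephos` — λ = 0.01, saturated constants, k_auto = ln 2/5 min⁻¹
  (5-minute RR‑P half-life), R_T = 25, H_T = 0.25 µM; the plateau
  (~2.3 µM ≪ R_T) and weak sensitivity (n_H ≈ 1.9) reproduce the damped
  switch, which sharpens monotonically (to n_H ≈ 14) as k_auto is lowered
  three decades.

Basal-activity study design: the basal phosphatase ladder sweeps the
catalytic factor over {0, 0.01, 0.1, 1} with the H–Rp association fixed at a
weak, kinetically first-order scale (0.005).  At the regulated-path
association strength the catalytically dead H·Rp complex acts as a dead-end
sequestrant of the kinase and drives the model into the degenerate
slow-manifold regime described above, scrambling the ladder; the weak-binding
design preserves the phenomenology under study — an unregulated phosphatase
flux progressively destroys ultrasensitivity — in a well-conditioned,
monostable model.

## Problem sizes

Oracle-equivalence grids use 100 random regime-interior parameter sets per
reduction; Monte-Carlo recovery uses 20 replicates of 12-point titrations at
5% CV; response curves use 12–15 log-spaced points.  These sizes give
seed-stable worst-case statistics (checked across several seeds) while a full
acceptance run completes in well under a minute.

## Known limitations

* The reductions are asymptotic: validity degrades continuously outside the
  declared windows (the solvers warn, not extrapolate silently).
* The basal model with a strongly binding basal phosphatase is numerically
  degenerate (and structurally close to dead-end-complex bistability
  motifs); curve metrics there carry ~0.5% irreducible uncertainty.
* No transcriptional autoregulation layer, no stochastic kinetics, no
  spatial structure beyond the two-compartment volume bookkeeping, and no
  continuation/bistability analysis — the implemented variants are
  monostable in their study regimes.
* Fitted standard errors are local (Gauss-Newton) quantities; strongly
  correlated parameter pairs are flagged, not resolved.
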