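# Methods

## The hydrodynamic model and its closed form

The package describes the motion of polymer–payload structural units on
continuous, non-differentiable (multifractal) curves.  Averaging over scale
resolutions yields a hydrodynamic pair for the differentiable velocity V and
state density ρ:

- momentum: ∂ₜV + V∂ₓV = (σ²/2)·∂ₓ[(∂ₓₓ√ρ)/√ρ]
- continuity: ∂ₜρ + ∂ₓ(ρV) = 0

with a quantum-like (Bohm) potential whose strength is set by the
diffusion-like coefficient σ.  For the initial conditions V(x,0) = V₀ and
ρ(x,0) = π^(−1/2)α^(−1) exp(−x²/α²), with ρ → 0 at ±∞ and V = V₀ on the
comoving line x = V₀t, the solution is the familiar free Gaussian packet in
Madelung form:

- V(x,t) = [V₀α² + (σ/α)²xt] / D(t)
- ρ(x,t) = π^(−1/2) D(t)^(−1/2) exp[−(x−V₀t)²/D(t)],  D(t) = α² + (σ/α)²t²

The coefficient σ²/2 in the momentum equation is the unique multiple under
which these fields are an exact solution (verified symbolically during
development); it corresponds to the identification σ = ħ/m in the quantum
analogue.  `pde_residual` provides an independent finite-difference oracle:
centered second-order differences of the analytic fields, whose maximum
defect converges to zero at second order in the grid spacing.  The summary
statistic weights the momentum defect by the normalized density and masks
the continuity defect where ρ/ρ_max < 10⁻³: outside the packet the 1/√ρ
factor of the quantum term amplifies discretization error in a region that
carries no material, and the weighted form is the physically meaningful
momentum-density balance.  Tolerances are convergence-order based (observed
refinement ratios 3.5–4.0 for halved spacing), not absolute.

## Scale relation and fractality degree

σ = λ·dt^(2/f(α)−1) links the coefficient to the effective fractal
dimension f(α) of the motion curves, with λ the fractal/non-fractal
transition coefficient and dt the scale resolution.  The singularity
spectrum is used as a single effective scalar per release stage; no
α-dependence is modelled.  The inversion
f = 2/(1 + ln(σ/λ)/ln dt) requires dt ≠ 1 and is monotone increasing in σ
for dt < 1, so decreasing μ (hence σ) maps to decreasing f(α).  λ, dt, τ₀,
α, V₀ have no fixed magnitudes in this problem; they are configuration with
unit-scale defaults (λ = 1, dt = 0.1, τ₀ = 1 h, α = 1, V₀ = 1), and τ₀ = 1 h
makes the nondimensional time η numerically the time in hours, keeping μ
interpretable as an inverse time scale.

## Release law conventions

Release is read as the density depletion at a fixed observation coordinate
ξ_obs (default 0, the density peak, i.e. the matrix position): the source
narrative never states where the derivative of ρ̄ is taken, so the package
makes it explicit and configurable.  The cumulative form is normalized by
ρ̄(ξ_obs, 0) so that m̄₀ is directly the asymptotic released fraction
regardless of ξ_obs.  The printed dimensional density was corrected in two
places before adoption — prefactor exponent −1/2 and a squared displacement
in the exponential — since only that form satisfies the stated initial
condition, stays normalized (∫ρ dx = 1 for all t), and reduces to the
nondimensional density under the substitutions above.  The symbols m̄ and
m₀ that appear interchangeably around the mass-release relation are treated
as one parameter m̄₀.  Exponential arguments are clipped at ±700
(saturation, not an error) to avoid overflow at extreme parameters.

## Classical kinetics conventions

- The first-order model follows the printed form log₁₀Q = kt (log of the
  *released* amount); the textbook log-of-remaining variant is available via
  `first_order_remaining=True`.
- All linear fits include a free intercept, because stages 2–3 start from
  nonzero release; the reported constant is the slope (Korsmeyer–Peppas:
  n = slope, K = 10^intercept).
- Korsmeyer–Peppas uses only points with M_t/M_∞ ≤ 0.6 by default (the
  conventional validity window), switchable off.
- Time is in hours everywhere; Q is the fraction of total payload (W₀ = 1
  for Hixson–Crowell).
- Stage-wise reports fit each stage in stage-local coordinates — time from
  the stage boundary, release as the increment over the previous stage's
  terminal value — so each stage is its own incremental dissolution
  experiment.  Replicates are averaged per time point before fitting;
  per-replicate fitting and optional isotonic (pool-adjacent-violators)
  cleanup are available.

## Stage calibration

Stage boundaries are fixed calendar values (5 h, 269 h, 840 h),
configurable; no change-point detection is attempted because the stages are
defined narratively.  Each stage is fitted by trust-region least squares of
M̄(η) + offset against the observed cumulative fraction, with bounds
μ ∈ [0, 100], φ ∈ (0, 100], m̄₀ ∈ (0, 1.5], a 3×3×3 multi-start grid
{0.1, 1, 10} per parameter (m̄₀ starts clipped to its bound), best residual
winning and ties broken deterministically by the lowest μ.  Non-convergence
is reported as a flag with diagnostics, never an exception.  The fitted μ
is reported both raw and as f(α) through the scale relation under the
configured (λ, dt).

Parameter recovery was characterized on a 24-point grid spanning the active
release (η = 0.25…6 for the reference parameters μ = 2, φ = 1, m̄₀ = 0.46):
noise-free recovery is exact to optimizer precision, and with 2 %
multiplicative noise the median relative error of μ over 50 seeds is ≈10 %.
Identifiability degrades when most observations sit on the saturated
plateau, since only the rising part of the curve constrains μ against φ.

## What the generator emulates — and what it does not

The generator reproduces the study design: the eight-row composition table
(including its printed-percent convention, where the exact ratio 2/3 is
printed truncated as 66), specimens normalized to 50 mg payload, 10 mL
medium with 1 mL withdrawal/replacement at each sampling time, hourly
sampling on day 1 then daily through day 35 (58 points), duplicate
replicates, and 3 % relative multiplicative Gaussian noise on measured
concentrations as a stand-in for NMR quantification error.  Withdrawal
mechanics remove 1/10 of the dissolved mass at each sampling; the
mass-balance correction Vc·Cᵢ + Vs·Σ_{j<i}Cⱼ inverts this exactly, which the
round-trip tests exploit.

The true curve is piecewise: first-order burst pinned to 46 % at 5 h,
square-root (Higuchi-type) diffusive stage pinned to 75 % at 269 h, and
first-order erosion tail pinned to 99 % at 840 h.  The stage shapes are a
modelling construction — the source describes the stages only narratively —
chosen so the burst stage is adequately fitted by all five classical models
while the erosion tail defeats all but the power law, mirroring the
reported adequacy pattern.  The rate constants realizing that pattern with
margin were fixed by a design study over the full formulation panel:
k₁ = 0.1 /h (stage-1 adequacy minimum r² 0.92, binding model first-order)
and k₃ = 0.0065 /h (stage-3 Korsmeyer–Peppas minimum r² 0.93 while
zero-order, first-order and Hixson–Crowell all stay below 0.85; Higuchi
remains adequate, which the "all but the power law" reading tolerates).
Formulation effects enter as a multiplicative speed factor (crosslinking
ratio 1.5 → ×1.1; payload 66 % → ×1.15, 33 % → ×0.9) applied to the stage-1
rate and the stage-2 time scale; because stages are pinned to their
milestones, the factor shapes the within-stage transient without moving the
milestones, which also makes the stage-3 behaviour payload-independent by
construction.  The stated timeline (day 1 + 11 days + 23 days vs "35
days") is internally off by about a day; the package fixes t_final = 840 h
and keeps the 269 h boundary.

Passing tests on this generator demonstrate the correctness of the
analysis chain and its statistical behaviour under the assumed noise model;
they do not validate the multifractal law against real dissolution data,
nor do they capture reservoir depletion physics, swelling/erosion dynamics,
pH/temperature effects, or correlated measurement error.

## Numerical and interface choices

- All randomness flows from one integer seed through `numpy` seed
  sequences (per-formulation and per-replicate child streams);
  (config, seed) → byte-identical outputs.
- CSV is the only tabular format (UTF-8, "." decimal, mandatory header);
  times in hours; every output file is stamped with the tool version and a
  12-hex-digit configuration hash.  Unknown configuration keys are rejected
  by name.
- Problem sizes in the test suite: PDE oracle grids up to 201×201,
  Monte-Carlo recovery at 50 seeds, panel analyses over the six urea-bearing
  formulations — sizes at which every behaviour checked is already stable.

## Known limitations

- The multifractal fit is validated by self-consistency and qualitative
  trajectory only; no fitted (μ, φ, m̄₀, f(α)) reference values exist to
  compare against.
- The f(α) values depend on the configured (λ, dt); only orderings and
  dispersions across stages/formulations are scale-free conclusions.
- The adequacy threshold r² ≥ 0.90 and stage-3 CV threshold 0.15 are
  package conventions, configurable, not derived quantities.
- One-dimensional geometry only; the law is not solved for arbitrary
  initial conditions.
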