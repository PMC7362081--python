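# mfrelease

Modelling of controlled release from polymer matrices — classical
dissolution kinetics plus a multifractal hydrodynamic release law — built
around the in vitro urea-release study design for chitosan/salicylaldehyde
xerogel formulations.  Intended for researchers analysing cumulative
release profiles (fertilizer or drug) who want, in one place: the five
standard kinetic fits, a stage-wise calibration of a two-parameter
multifractal release law, and a faithful simulator of the
withdrawal/replacement sampling protocol for validating the whole chain
offline.

## The models

**Classical kinetics.**  Cumulative released fraction *Q(t)* is fitted on
the linearized forms of the zero-order (*Q = k₀t*), first-order
(log₁₀ *Q* = *kt*), Higuchi (*Q = k_H √t*), Korsmeyer–Peppas
(*M_t/M_∞ = K tⁿ*) and Hixson–Crowell (*W₀^⅓ − W_t^⅓ = kt*) laws, each by
ordinary least squares with a free intercept, reporting *r²* and an
adequacy flag (*r² ≥ 0.90* by default).

**Multifractal hydrodynamic law.**  Structural units of the polymer–payload
complex are assumed to move on continuous but non-differentiable
(multifractal) trajectories.  At fixed scale resolution the dynamics reduce
to a Madelung-type momentum/continuity pair whose solution for a Gaussian
initial density is a translating, spreading Gaussian.  In nondimensional
coordinates (ξ, η) the density is

ρ̄(μ, φ, ξ, η) = (1 + μ²η²)^(−1/2) · exp[ −(ξ−η)² / (φ²(1+μ²η²)) ]

with μ = στ₀/α² the fractality-degree parameter and φ = α/(V₀τ₀) the width
parameter.  Released mass follows the density depletion at the matrix
position: dM̄/dη = −m̄₀ dρ̄/dη, so the cumulative release is
M̄(η) = m̄₀[1 − ρ̄(0, η)] at ξ_obs = 0.  The scale relation
σ = λ·dt^(2/f(α)−1) converts a fitted μ into an effective fractality degree
f(α).

**Three-stage pipeline.**  Release profiles are segmented at fixed calendar
boundaries (burst ≤ 5 h; diffusive stage to 269 h; erosion tail to 840 h),
each stage is calibrated separately as an incremental release with
multi-start trust-region least squares, and the per-stage f(α) values form a
fractality trajectory.  Across formulations, the coefficient of variation of
stage-3 f(α) quantifies independence of the late-stage behaviour from the
initial payload percentage.

**Synthetic protocol.**  The generator reproduces the study design: eight
formulations (two crosslinking ratios × payload 0/33/50/66 %), specimens
normalized to 50 mg urea in 10 mL medium, 1 mL withdrawn and replaced at
every sampling time (hourly on day 1, daily to day 35), duplicate
replicates, 3 % multiplicative measurement noise, and a three-stage true
curve hitting 46 % at 5 h, 75 % at 269 h and 99 % at day 35.  The
mass-balance correction `correct_sampling` inverts the withdrawal dilution
exactly.

## Worked example

```sh
mfrelease simulate --outdir demo --seed 1
mfrelease report --input demo/panel.csv --outdir demo --seed 1
```

prints

```
wrote demo/panel.csv (12 profiles)
mfrelease report | 6 formulation(s)
  1.5-U0.5: f(alpha) by stage = 1.55, 0.844, 0.677 | strictly decreasing: True
  1.5-U1: f(alpha) by stage = 1.58, 0.886, 0.666 | strictly decreasing: True
  1.5-U2: f(alpha) by stage = 1.6, 0.905, 0.671 | strictly decreasing: True
  2-U0.5: f(alpha) by stage = 1.57, 0.895, 0.677 | strictly decreasing: True
  2-U1: f(alpha) by stage = 1.55, 0.877, 0.678 | strictly decreasing: True
  2-U2: f(alpha) by stage = 1.58, 0.919, 0.669 | strictly decreasing: True
  stage-3 fractality CV = 0.0063 | load-independent: True
```

Reading: each formulation's fitted fractality degree f(α) falls from ≈1.6
in the burst stage to ≈0.9 in the diffusive stage and ≈0.67 in the erosion
tail — the release becomes progressively less "energetic" — and the
stage-3 degrees are nearly identical across payloads (CV 0.006 ≪ 0.15), so
the late-stage behaviour does not depend on how much urea was loaded.
`fit-classical` writes the per-stage adequacy table of the five kinetic
models (`classical_fits.csv`); on the default panel all five fit the burst
stage while only Korsmeyer–Peppas survives in the erosion tail.

The same is available as a library:

```python
from mfrelease import GeneratorConfig, generate_panel, fit_all_stages, fractality_trajectory
profiles, manifest = generate_panel(GeneratorConfig(), seed=1)
fits = fit_all_stages([p for p in profiles if p.formulation_code == "2-U1"])
print(fractality_trajectory(fits))
```

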