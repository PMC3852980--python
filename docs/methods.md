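# Methods

## Model

The package implements the free-solvent description of osmotic equilibrium
for a two-chamber membrane osmometer. Chamber II contains the
macromolecule, chamber I only diffusible species; at equilibrium the
osmotic pressure satisfies

    π = −(RT / V̄₁) · ln(a₁ᴵᴵ / a₁ᴵ)

with a₁ the solvent activity and V̄₁ its partial molar volume. Two
composition variables are used:

- **Total water mole fraction** x₁ = N₁ / (N₁ + Σ proteins + Σ dₖNₖ),
  every water counted, salts counted as dₖ dissociated ions per formula
  unit (d = 2 for NaCl/KCl, 1 for non-electrolytes).
- **Free water mole fraction** x̂₁: each macromolecule j is first assigned
  νᵢⱼ mol of bound species i (water and salt); bound amounts are removed
  from both numerator and denominator, and the hydrated macromolecule
  counts as a single particle. A bound salt formula unit removes dₖ
  ion-moles from the free-ion count.

The free-solvent postulate is that the solution is *ideal in x̂₁*, so
π = −(RT/V̄₁) ln(x̂₁ᴵᴵ/x̂₁ᴵ). Equating the non-ideal law in x₁ with the
free-solvent law in x̂₁ yields the closed-form activity coefficient of
free-solvent, γ₁ᴵᴵ = (x̂₁ᴵᴵ/x₁ᴵᴵ)(x₁ᴵ/x̂₁ᴵ); the protein-free chamber is
ideal by construction (x̂₁ᴵ = x₁ᴵ, γ₁ᴵ ≡ 1, exposed read-only). The
inverse route, γ₁ᴵᴵ = (x₁ᴵ/x₁ᴵᴵ)·exp(−πV̄₁/RT), back-calculates γ₁ from
measured pressures; the two are exact inverses through the forward model,
which the test suite verifies to 1e-10 relative over a thousand random
feasible compositions.

Assumptions inherited from the model: solute–solvent interactions only (no
protein–protein association terms), a single solvent, binding
stoichiometries independent of concentration, and chamber-I salt taken as
prepared (no Donnan/charge-balance correction).

## Parameters

| parameter | units | default | origin |
|---|---|---|---|
| hydration ν₁₂ | mol H₂O/mol | SASA monolayer | (SASA Å²/100) × 15.2 waters/nm² |
| ion binding ν₃₂ | mol salt/mol | scenario value | Scatchard-type two-site measurements (BSA: 11.59/10.62/8.81 at pH 4.5/5.4/7.4; Hb: 6) |
| monolayer coverage | waters/nm² | 15.2 | literature monolayer density |
| M (BSA, Hb, sucrose, H₂O) | g/mol | 66 430, 69 700, 342.30, 18.015 | full-precision values; required to reproduce tabulated 3-decimal hydrations |
| v̄ (partial specific volume) | mL/g | 0.733 protein, 0.61 sucrose | globular-protein consensus; config knob |
| ρ_w | g/mL | 0.997 | water at 25 °C; config knob |
| V̄₁ | m³/mol | M_w/ρ_w × 10⁻⁶ ≈ 1.807e-5 | derived unless supplied |
| R | J/(mol·K) | 8.314462618 | CODATA |

Hydration interconversions: g/g = (mol/mol)·M_w/M_macro, exact inverses to
machine precision. Pressures are Pa internally; the CLI and dataset I/O
convert mmHg/atm/kPa/psi (1 atm = 101 325 Pa, 1 mmHg = 133.322 Pa).

**Mole accounting for g/L recipes.** Osmometry series are reported as
protein g/L and salt molarity, which do not by themselves fix N₁. The
package uses excluded-volume accounting: water fills the basis volume not
occupied by protein, N₁ = ρ_w(1000·V − C·V·v̄)/M_w, with the salt's own
volume neglected (≤1% of volume at 0.15 M). This is a documented package
choice — the genre's data tables do not state their water bookkeeping —
and both v̄ and ρ_w are exposed so alternative conventions can be dialed
in. Recipes with C·v̄ ≥ 1000 mL/L are rejected as infeasible.

**Saturation boundary.** If bound water (or salt) would exceed the amount
present, the model has left its domain of validity; the package raises an
`InfeasibleBindingError` naming the species rather than clamping. During
regression these points receive a large finite residual (1e8 Pa) so the
optimizer retreats from the boundary without ever evaluating an invalid
state.

## Estimator and regression

`FreeSolventModel` is a scikit-learn-style regressor: X is one column of
concentrations (g/L), y osmotic pressures (Pa). `predict` is the pure
physical forward model (usable without fitting, since both parameters are
independently measurable); `fit` regresses whichever of (ν₁₂, ν₃₂) are
flagged free by bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective,
finite-difference Jacobian, tolerances 1e-12). Default bounds are
ν₁₂ ∈ [0, 12 000] mol/mol and ν₃₂ ∈ [0, 50]; hydration is fitted in
mol/mol and reported in both unit conventions. Residuals are absolute Pa
by default; a relative-weighting flag divides by max(|y|, 1 Pa). Standard
errors come from the local quadratic model, σ²(JᵀJ)⁻¹ with σ² the reduced
sum of squares. Non-convergence sets `converged_ = False` rather than
raising. `fit_binding_parameters` wraps the estimator for dataset objects
and seeds the fit from a supplied SASA (monolayer hydration) or the
bound-box midpoints.

## Synthetic data

The generator evaluates the forward model on a concentration grid and
applies seeded noise: none, multiplicative Gaussian (π·(1+σε), σ a
relative fraction — the default study condition is σ = 0.02, matching the
few-percent scatter of careful membrane osmometry), or additive Gaussian
(Pa). Preset scenarios reproduce the five canonical systems: BSA in
0.15 M NaCl at 298.15 K for pH 4.5/5.4/7.4 (hydration 1.144 g/g default,
range 1.144–1.162 across surface programs; ion binding 11.59/10.62/8.81),
sheep hemoglobin in 0.1 M KCl at 273.15 K (0.973 g/g, range 0.955–1.025;
ν₃ = 6) and sucrose in water at 303.15 K (0.316 g/g default, range
0.184–0.316 = 3.5–6 mol/mol; no ion binding). Default grids are 20 points
over 0–475 g/L (proteins) and 0–900 g/L (sucrose), the spans of the
classic datasets.

What the generator does *not* emulate: pH-dependent conformational
change, protein–protein interactions near saturation, membrane leakage or
baseline drift, and concentration-dependent binding. Passing
parameter-recovery tests on this generator therefore demonstrates the
identifiability and correctness of the estimation machinery under the
model's own assumptions, not robustness to real-data artifacts.

## Numerical choices

- **Cancellation-free pressures.** x₁ᴵᴵ/x₁ᴵ is within ~1e-6 of 1 in
  dilute solutions, so a float `log(x_II/x_I)` retains as little as 5
  digits of the pressure. The pressure routines instead form
  x_II/x_I − 1 exactly (rational arithmetic on the mole inventories via
  `fractions.Fraction`) and finish with `log1p`, making π accurate to a
  few ulp at every concentration. The test suite checks this against an
  independent 50-digit `decimal` evaluation at 1e-12 relative.
- With ν ≡ 0 the free and total mole fractions are computed through the
  same exact-rational path, so zero-binding ideality (γ = 1, free-solvent
  π = ideal π) holds *exactly*, not just to tolerance.
- γ > 1 is physically unusual (it needs ion binding to outweigh
  hydration) but algebraically permitted; the package warns and reports
  the value rather than clamping.
- Printed-value comparisons round half away from zero to 3 decimals,
  matching tabulation conventions.

## Behavior worth knowing

- π is strictly increasing in concentration and in hydration ν₁₂, but
  *decreasing* in ion binding ν₃₂: binding salt removes free ions from
  chamber II only, lowering the osmotic driving force (equivalently,
  raising γ₁ toward 1).
- For BSA at pH 4.5 with the minimum hydration (1.144 g/g, ν₃ = 11.59)
  the ion-binding and hydration terms nearly cancel at infinite dilution:
  the exact slope of γ₁ at C → 0 is proportional to
  2ν₃ − 2ν₁N₃/N₁ = 23.18 − 22.9 > 0, so γ₁ rises about 7×10⁻⁸ above
  unity below ~20 g/L before the hydration term (which grows as free
  water depletes) dominates. At any plotted resolution the curve
  decreases monotonically from 1; tests assert strict decrease from
  20 g/L and γ ≤ 1 + 1e-7 everywhere. The other scenarios decrease
  strictly from 0.

## Problem sizes

Property suites use 1000 random feasible compositions for the round-trip
identity, 100 for oracle equivalence, and 200 for zero-binding ideality.
Parameter recovery uses 15 concentrations spanning 50–450 g/L, with 20
replicates at 2% multiplicative noise; the noise-calibration check uses
1000 replicates of a single composition. These sizes give stable
statistics while keeping the full suite around a couple of seconds.

## Limitations

- Single macromolecule species; the multi-protein generalisation of the
  mole-fraction bookkeeping is implemented in the chamber/binding types
  but presets, estimator and CLI target the one-protein case.
- No Gibbs–Duhem propagation to protein or salt activity coefficients.
- No SASA computation from structures — SASA is an input, by design.
- No Donnan-potential or charge-balance modeling of chamber-I salt.
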