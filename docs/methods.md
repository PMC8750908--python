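# Methods

## Model and assumptions

The package models transport of a magnetizable solute in a *uniform*
static field. The only magnetic driver retained is the
concentration-gradient force density f = χB²∇n/2μ₀; the magnetic-gradient
force is smaller by the factor 2(∇B/B)(n/∇n) — of order 10⁻⁹ under MRI
conditions, which `gradient_force_ratio` quantifies — and Lorentz-force
effects on diffusion are outside the model entirely. The solute drifts
with Nernst–Einstein mobility γ = D/k_BT; substituting u = γf₁ into the
advection–diffusion equation collapses the advective term into a rescaled
Fickian equation with

    D_eff = D(1 − β),   β = χB²/(2μ₀RT).

Assumptions inherited by everything downstream: χ is constant (no Curie
temperature dependence), concentrations are dilute enough for D to be
concentration-independent, and the field is strictly uniform.

For 0 ≤ β < 1 the characteristic time is exactly τ_eff = τ₀/(1−β) with
τ₀ = L²/D. For β < 0 the same exact form applies (the time *shrinks*);
τ₀(1+β) is only its small-|β| linearization. A printed variant τ₀(1−β)
for the diamagnetic branch is inconsistent with D_eff = D(1−β) and with
the statement that diamagnetic diffusion speeds up, so the exact form is
used everywhere and the linearization is mentioned only here.

At β ≥ 1 the effective diffusivity is non-positive ("squeezing" of
paramagnetic solute). Whether negative diffusion coefficients are
physical is contested; the calculators therefore report β and a
`supercritical` regime/flag but no code path ever integrates the PDE with
D_eff ≤ 0 — the solvers raise `DiffusionSuppressedError`.

## Parameters

| parameter | units | default | why |
|---|---|---|---|
| T | K | 300 | the temperature at which all eight tabulated onset fields reproduce at 3 s.f.; every function takes T explicitly |
| R (gas constant) | J/(K·mol) | 8.31 | the two-decimal value the onset table is computed with; `PhysicalConstants` accepts CODATA overrides, with a 0.1% consistency check R/N_A ≈ k_B |
| β₀ | — | 0.05 | a 5% change in characteristic time, the conventional detectability onset |
| χ | m³/mol | per species | SI *molar* susceptibility, signed; whole-cell volume susceptibilities are stored as annotations only and rejected as inputs |
| D_Hb | m²/s | 1.6×10⁻¹¹ | the larger of the two published hemoglobin diffusivities — the one the τ_Hb ≈ 1 s estimate is built on; 3.4×10⁻¹² kept as an alternative |
| D_ox | m²/s | 10⁻⁹ | O₂ diffusivity inside an erythrocyte |
| RBC a / R_c | m | 3×10⁻⁶ / 4×10⁻⁶ | diffusion length scale vs mean cell radius for the pressure estimate |
| n_Hb | mol/m³ | 5.5 | intracellular hemoglobin concentration; membrane-pressure gradient is the volume average ∇n = n_Hb/R_c |
| trapping window | s | 0.01–0.1 | O₂-capture-by-Hb time range, the middle rung of the time hierarchy |
| alveolar transit | s | 0.8 | residence time in a lung alveolus; τ_Hb,eff above it flags `saturation-risk` |

Registry note: two FeCl₃ susceptibilities circulate (+2.573×10⁻⁸ and
+1.345×10⁻⁸ m³/mol); the registry stores the former, which is the value
the 110 T onset field corresponds to, and records the other in the notes.

The RBC report at 20 T illustrates a deliberate choice: τ_Hb,eff ≈ 0.585 s
is *below* the 0.8 s transit, so the report exposes both numbers and the
flag logic rather than asserting an oxygen-saturation effect; the
`saturation-risk` flag fires only when the computed inequality actually
holds. Membrane pressure is computed for the fully deoxygenated cell only
(an oxygenated cell's Hb is diamagnetic and the effect vanishes); the
significance comparator is the 10–150 Pa mitotic rounding band, the only
quantitative cellular pressure scale available.

## Sphere solutions

Boundary conditions: surface held at n₀, initially empty interior. The
series prefactor is the standard 2R/(πr) (the only form consistent with
the uptake series under volume integration), and the nominal center
condition "n(t,0) = 0" is interpreted as regularity at the origin — the
series itself gives n(t,0) > 0 for every t > 0. At r = 0 the analytic
limit 1 + 2Σ(−1)^k exp(−k²π²τ) is evaluated directly instead of dividing
by r.

Truncation: terms are summed until the exponential tail drops below
`tail_tolerance` (10⁻¹⁰), capped at `max_terms` (200). Convergence slows
as τ = D_eff t/R² → 0; below τ = 10⁻⁴ a `SeriesAccuracyWarning` is
attached (the CLI surfaces it in the JSON output). Raw point evaluations
are never clamped; exported grids clamp to [0, 1] to suppress Gibbs
over/undershoot near t = 0.

The finite-difference route substitutes w = r·n, which turns the radial
operator into the 1D heat equation and removes the coordinate singularity
exactly; w(0) = 0, w(R) = R·n₀. Time stepping is implicit-centered
(θ = 1/2, unconditionally stable, second order in both Δr and Δt), with
the first two steps taken at θ = 1 (backward Euler): a θ = 1/2 step is
not monotone on the discontinuous start (empty interior against a held
surface) and would oscillate; two damped startup steps restore the
discrete maximum principle without any clamping. The center value is
recovered from the first two interior nodes by Richardson extrapolation
of w/r (second order, exploiting even symmetry of n in r). The numeric
uptake integral normalizes by the trapezoid quadrature of r² itself
rather than the exact R³/3, cancelling the quadrature bias so a uniform
field integrates to exactly 1.

Cross-validation (the `validate` subcommand and the acceptance suite)
compares the two routes on the uptake-figure geometry R = 5 μm,
D = 10⁻⁹ m²/s for β ∈ {+0.5, 0, −0.5} at dimensionless times
τ ∈ {0.02, 0.05, 0.1} on a 201 × 2000 grid; the measured maximum
discrepancy is ≈3×10⁻⁵, and halving the spatial step reduces the error
against the series by the factor ≈4 expected of a second-order scheme.
Comparisons are made at τ ≥ 0.02 because at τ → 0 the truncated series is
itself Gibbs-limited and neither route is a reference for the other.

## Fixture generator

Property tests draw seeded random tuples (χ, B, T, D, R, β₀): |χ|
log-uniform over 10⁻⁹–10⁻⁶ m³/mol with random sign (bracketing the
registry, small ions to proteins), B uniform on 0–100 T (up to the
strongest static laboratory fields), T uniform on 270–320 K, D log-uniform
over 10⁻¹²–10⁻⁹ m²/s, R log-uniform over 1–10 μm, β₀ log-uniform on
(10⁻³, 0.9) so the β ↔ B₀ round-trip is always defined. The generator
emulates parameter *ranges*, not correlations: real species pair χ and D
in physically linked ways the generator ignores, so passing property
tests demonstrate algebraic identities (quadratic field scaling, 1/T
scaling, round-trips) over the whole parameter box, not biological
realism of any single tuple. Same seed → byte-identical fixture files.

## Numerical edge cases and tie-breaks

* `onset_field` uses |χ| so diamagnets have an onset; `critical_field`
  requires χ > 0 (diamagnetic diffusion is never suppressed).
* Regime classification: `supercritical` iff β > 1, `near-critical` for
  0.95 ≤ β ≤ 1, otherwise by |β| against the 0.05 onset; boundary values
  land on the stronger label.
* β at the 3-s.f.-rounded onset fields recovers 0.05 to ~0.5% except near
  110 T, where 3 s.f. resolution is 0.45% in B, hence up to ~0.9% in β
  (quadratic); tests bound this at 1%.
* t = 0 returns the initial data exactly (uptake 0) rather than summing a
  non-convergent series.
* CSV outputs use shortest-repr floats and round-trip bit-for-bit (read
  back with pandas `float_precision="round_trip"`); no timestamps in data
  files.

## Problem sizes

The validation grid is 201 radial nodes × 2000 time steps (three field
cases), the convergence study 51→101 nodes at 8000 steps, and the
property sweeps use 1000 fixtures — sizes at which every check runs in
seconds on one core while leaving the FD error 30× inside the 10⁻³
acceptance bound.

## Known limitations

* No Lorentz-force or field-gradient transport; strictly uniform B.
* χ constant in T (no Curie law); χ and D uncorrelated in fixtures.
* Analytic path requires an empty initial sphere; general g(r) only via
  the FD solver.
* No oxygen–hemoglobin binding kinetics, membrane elasticity, rupture
  mechanics, or partial oxygenation states: the RBC report composes
  closed-form estimates, it does not simulate a cell.
* β ≥ 1 dynamics are deliberately unimplemented (ill-posed backward
  diffusion); only reported as a flag.
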