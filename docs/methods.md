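# Methods

## Quantities and conventions

All energies are molar transition energies `E_T` in kcal/mol, computed
from band maxima as `E_T = 28590/λ_max(nm)`; the constant is kept exactly
at 28590 so that outputs are comparable with the solvatochromic
literature, which tabulates it in that form. `x2` is always the bulk mole
fraction of the **protic/polar cosolvent** S2; the base solvent S1 has
`x1 = 1 − x2`. Users loading their own tables must map their columns to
this convention. Compositions are mole fractions throughout; no
volume-to-mole conversion is provided (it needs densities the package
does not carry).

The band-maximum reading uncertainty of such measurements (~±0.5 nm) is
not propagated through the fits; it only motivates the default synthetic
noise level (below).

## Kamlet–Abboud–Taft regression

`E_T = E_T⁰ + a·π* + b·α + c·β`, fitted by ordinary least squares with an
intercept, unweighted — with ten-ish solvents and no stated error model
there is nothing to gain from anything fancier. The descriptor convention
is the universal one: π* dipolarity/polarizability, α HBD acidity, β HBA
basicity. The design matrix `(1, π*, α, β)` must have full column rank;
rank deficiencies are reported with the names of the collinear columns.
Descriptor panels are user-supplied; `reference_kat_panel()` ships a
clearly synthetic stand-in (widely tabulated descriptor values with
energies generated from the reported relation), intended for smoke tests
and demos, not as anyone's measured panel.

## Shell composition

The simple two-state reading `x2ˢ = (E_T − E_T1)/(E_T2 − E_T1)` uses
pure-solvent energies as the scale; these default to the measured x2=0 /
x2=1 rows and can be overridden with explicitly measured values. For
synergistic mixtures (`E_T12` outside the [E_T1, E_T2] range) the formula
can return `x2ˢ` outside [0,1]; such points are flagged, never clipped, so
synergism stays visible in the output. `δ_s,2 = x2ˢ − x2` is reported
dimensionless (it is a difference of mole fractions). Extrema of `δ_s,2`
are reported over the measured grid only; sign crossings are located by
linear interpolation between the two bracketing grid points, which is the
only interpolation performed. Because the literature uses "excess energy"
for at least two different summaries, `excess_energy_summary` emits both
the extreme signed deviation from the ideal line and its trapezoid
integral over `x2`, labelling neither as canonical.

## Exchange model

Local shell fractions are the normalized weights
`(1−x2)^m : f2/1·x2^m : f12/1·(x2(1−x2))^(m/2)`. The cross-term exponent
is `m/2`: building one S12 complex consumes half an exchange unit of each
solvent, and the model's m = 2 special case is universally written with
the power 1. Some presentations print the power as `m`; a strict
`cross_exponent="printed"` mode evaluates that form for comparison (the
two coincide at no `m`, but fitted parameters are usually similar).
Endpoints are handled analytically, so `E_T(0) = E_T1` and
`E_T(1) = E_T2` hold exactly for both variants, including the corrected
one (the correction term carries factors of `x2²` and `(1−x2)²`).

Fitting is bounded nonlinear least squares (scipy trust-region
reflective, `x_scale="jac"`). Free parameters: `E_T1, E_T2, E_T12`
(bounded to the data range ±5 kcal/mol), `f2/1, f12/1 ≥ 0` (nonnegative
by construction — they are ratios of shell and bulk proportions), and
for the corrected variant `k` (unbounded). `m` is a fixed hyperparameter
chosen per fit — exchange orders are small integers in practice, and
`compare_model_variants` handles the discrete choice by ranking
candidates on (converged, stable, residual SD). Endpoints are *fitted* by
default (fitted tables in this literature list them as model outputs,
slightly different from the measured pure-solvent values); a
`fix_endpoints` option pins them to the measured ends.

Multi-start: 32 Latin-hypercube starts (seeded, so bit-reproducible) over
the bound box (f starts drawn in [0,5], k starts in [−10,10]) plus one
informed start (endpoints at the data ends, `E_T12` at the mid-grid
energy, f's at 1, k at 0). Tolerances 1e-12, at most 5000 evaluations per
start; the best converged start by RSS wins, ties (ΔRSS < 1e-12) going to
the lowest start index; the winner is re-polished at machine-level
`xtol`. A fit raises a non-convergence error carrying the per-start log
when no start succeeds.

**Stability flag.** The flag is raised when converged starts that *tie
the best RSS* (within 1e-9 relative) disagree on any parameter by more
than 1% relative. Restricting the comparison to tied starts makes the
flag a detector of non-identifiability — distinct parameter sets fitting
equally well, e.g. the f-ratios on a flat series — rather than of
ordinary local-minimum scatter among worse starts.

**Identifiability limit of k.** When |k| is small (≲0.01 kcal/mol), the
sign of k is not determined by a titration curve in double precision:
flipping `k → −k` together with compensating shifts of order 1e-4 in
`E_T12`, `f2/1`, `f12/1` reproduces the curve to ~1e-13 kcal/mol
everywhere, so both sign choices sit in one flat valley at the numerical
floor and no optimizer can separate them. The magnitude |k| and the
curve itself remain well determined. This matches the experimental
literature, where k is reported as undeterminable for weakly structured
mixtures. Tests therefore assert magnitude-and-curve recovery in that
regime, and full signed recovery when |k| is large.

## Statistical cell model

The printed form of the cell-model left side involves `1 − x1ˢ`, which in
a three-component shell equals `x2ˢ + x12ˢ` and does not linearize; the
working form here is the two-state log-odds `ln(x2ˢ/(1−x2ˢ))` regressed
on `ln(x2/x1)`, which is exact for complex-free shells (slope `m`,
intercept `ln f2/1` — used as a closed-form oracle in tests). A
`ln(x2ˢ/x1ˢ)` mode is available when a full local composition is
supplied. Boundary points, where a log is undefined, are dropped with a
warning rather than clipped; at least three interior points are required.
The intercept converts to the interaction-energy difference
`ω1 − ω2 = intercept · k_B · T` (SI joules, with a 1e-21 J convenience
scale); default temperature 295.15 K (ambient, 22 °C), overridable.

## Synthetic data

`simulate_exchange_series` is the forward exchange model plus i.i.d.
Gaussian noise on `E_T` (noise is applied to the energy, not the
wavelength, since the energy is the fitted quantity). Defaults: an
11-point even grid over `x2 ∈ [0,1]`, matching typical volumetric
titration series of 10–13 compositions, and σ = 0.05 kcal/mol, roughly
the energy jitter implied by a ±0.5 nm reading error on a band near
430 nm. `scenario_library()` encodes the eight studied binary mixtures
(water/DMSO/benzene/DMF + methanol, water + ethanol, DCE + octanol,
DMF + propanediol, dioxane + ethylene glycol) with their fitted parameter
sets, covering near-linear, hyperbolic, sigmoid and concave isotherm
shapes, three of them with the water-structure correction.
`simulate_lser_panel` draws descriptors uniformly from ranges spanning
common solvents (π* ∈ [0,1.1], α ∈ [0,1.2], β ∈ [0,1]) with rejection
resampling to guarantee a full-rank design.

What the generator does *not* emulate: band shapes and peak-picking
error, composition-dependent (heteroscedastic) noise, volumetric mixing
errors, impurity effects, or any deviation of real isotherms from the
exchange-model family. Passing round-trip tests therefore demonstrate
correctness of the estimation machinery under the model's own
assumptions, not validity of the model for any particular real mixture.

## Problem sizes and noise in the validation suite

Round-trip validation uses 21-point noiseless grids (recovery to 1e-3
relative or better for all identifiable parameters); property suites run
on 99-point grids; the optimizer-vs-grid-search bound uses 20 random
instances against a 3-values-per-parameter box; noisy-recovery checks use
100 seeded replicates at σ = 0.05 with a reduced 4-start schedule (the
informed start is always included, and the estimator is unchanged).

A note on what noisy recovery can achieve: with five free parameters on
an 11-point grid at σ = 0.05 kcal/mol, the Cramér–Rao bound on `f2/1`
for the strong-preference (benzene + methanol-like) truth is ≈ 0.47
(0.28 even with 21 points and endpoints pinned), so median absolute
errors of ~0.2–0.3 are the statistical floor, not an optimization
deficiency; the suite checks that the fitter attains this bound.

## Known limitations

- `m` is never optimized continuously; only values supplied as candidates
  are compared.
- No heteroscedastic weighting or error propagation from λ to `E_T`.
- The sign of small |k| is unidentifiable (see above).
- The cell model is fitted in the two-state approximation; for strongly
  complex-dominated shells its slope and intercept are effective
  parameters, not exchange constants.
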