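# prefsolv

Preferential-solvation analysis of solvatochromic indicators in binary
solvent mixtures.

## The problem

A solvatochromic dye dissolved in a mixture of two solvents S1 + S2 does
not, in general, see the bulk composition: its first solvation shell
(the cybotactic region) is enriched in whichever component interacts more
strongly with it. Because the position of the dye's charge-transfer
absorption band tracks the polarity of its immediate environment, a
titration of the band maximum against the bulk mole fraction `x2` of the
cosolvent is a direct probe of that enrichment. This package implements
the standard analysis chain for such titrations, for people studying
solvent effects on zwitterionic/betaine-type indicators:

1. **Spectroscopic conversion** — molar transition energies from band
   maxima, `E_T (kcal/mol) = 28590 / λ_max (nm)`.
2. **Kamlet–Abboud–Taft LSER** — ordinary least squares of
   `E_T = E_T⁰ + a·π* + b·α + c·β` over a panel of pure solvents,
   separating dipolarity/polarizability (π*), hydrogen-bond donor acidity
   (α) and acceptor basicity (β) contributions.
3. **Shell composition** — the model-free local cosolvent fraction
   `x2ˢ = (E_T − E_T1)/(E_T2 − E_T1)` and the preferential-solvation
   parameter `δ_s,2 = x2ˢ − x2`.
4. **Two-step solvent-exchange model** (Bosch–Rosés / Skwierczynski–
   Connors family) — the shell holds S1, S2 or the 1:1 complex S12, with

       x1ˢ ∝ (1−x2)^m,  x2ˢ ∝ f2/1·x2^m,  x12ˢ ∝ f12/1·(x2(1−x2))^(m/2)

       E_T = E_T1·x1ˢ + E_T2·x2ˢ + E_T12·x12ˢ  (+ ΔE_T)

   where `f2/1`, `f12/1` are exchange preferences, `m` the exchange order,
   and the optional water-structure correction
   `ΔE_T = k·f2/1·x2²·[(1−x2)² + f12/1·(1−x2)·x2/2] / [(1−x2)² + f2/1·x2² + f12/1·x2(1−x2)]²`
   captures structured water at low alcohol content. Parameters are
   estimated by bounded nonlinear least squares from a seeded
   Latin-hypercube multi-start.
5. **Statistical cell model** — the straight line
   `ln(x2ˢ/(1−x2ˢ)) = m′·ln(x2/x1) + (ω1−ω2)/k_B·T`, whose intercept gives
   the solute–solvent interaction-energy difference in units of k_B·T.

A seeded synthetic-data module generates titration series from the
exchange model (the library ships the eight studied mixture parameter
sets) and KAT panels from the fitted LSER, so the whole chain is testable
as a round trip without any measured spectra.

## Worked example

```python
import numpy as np
import prefsolv as ps

truth = ps.scenario_library()["Benzene + MeOH"]     # f2/1 = 2.17, f12/1 = 1.41
series = ps.simulate_exchange_series(truth, grid=np.linspace(0, 1, 21),
                                     mixture_name="Benzene + MeOH")
fit = ps.fit_exchange_model(series, variant="general", m=2,
                            options=ps.FitOptions(n_starts=32, seed=1))
print(f"f2/1 = {fit.params.f2_1:.4f}, f12/1 = {fit.params.f12_1:.4f}, "
      f"E_T12 = {fit.params.et12:.2f} kcal/mol, sd = {fit.sd:.2e}")
```

prints

```
f2/1 = 2.1700, f12/1 = 1.4100, E_T12 = 63.58 kcal/mol, sd = 1.08e-14
```

i.e. from a noiseless 21-point curve the optimizer recovers the generating
parameters to machine precision: the dye prefers methanol over benzene by
a factor 2.17 in its first shell, and the benzene–methanol complex has an
intermediate transition energy. The same chain runs from the shell, via
`ps.shell_series`, down to `ps.fit_cell_model` for interaction energies.

The numbered scripts under `analysis/` run the full study on synthetic
data — `01_simulate_series.py` through `05_cell_model.py` — writing tables
under `results/`. A `prefsolv` CLI (`simulate`, `fit-exchange`,
`fit-lser`, `shell`, `cell-model`, `analyze`) wraps the same functions for
shell use.

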