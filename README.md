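# odzrates

Nitrogen-cycle rate inference for the anoxic cores of oceanic
oxygen-deficient zones (ODZs), built around the hypothesis that nitrite
oxidation there proceeds without oxygen via **nitrite disproportionation**:

    5 NO2⁻ + 2 H⁺ → N₂ + 3 NO₃⁻ + H₂O

The package is aimed at marine biogeochemists who work with natural-abundance
nitrogen isotope profiles and ¹⁵N tracer incubations, and who want the full
chain from raw tables to process rates to be reproducible and testable.

## What it computes

**Inverse 1-D isotope model.** At steady state the net biochemical
production or consumption *R* of each pool (¹⁴NH₄⁺, ¹⁴NO₂⁻, ¹⁴NO₃⁻,
¹⁵NO₂⁻, ¹⁵NO₃⁻) is balanced by vertical eddy diffusion and advection,

    R(z) = w dC/dz − K_z d²C/dz²,

and at each depth the five *R* values are expressed in terms of four
process rates — nitrate reduction (*F*_Nar), denitrification (*F*_Nir),
anammox (*F*_Amx, with a nitrate side branch of *c* = 0.16 mol NO₃⁻ per mol
NH₄⁺), and disproportionation (*F*_Dis, as nitrate produced).  The ¹⁵N
balances divide each flux by its kinetic fractionation factor α and weight
it by the ¹⁵N/¹⁴N ratio of its substrate pool; disproportionation inherits
α_Dis = α_Nxr (inverse fractionation of nitrite oxidation) for its nitrate
branch and α_DisN2 = α_Nir for its N₂ branch.  The 5×4 system is solved per
depth by nonnegative least squares (`F ≥ 0`), statsmodels-style:
`InverseIsotopeModel(...).fit()` returns an `InversionResults` with rate
profiles, residual norms, active bounds, N₂-production breakdowns and a
`summary()`.

**¹⁵N tracer incubation rates.** Slopes of product accumulation versus time
(ordinary least squares with slope standard errors): nitrite oxidation from
excess ¹⁵NO₃⁻ divided by the nitrite-pool atom fraction *f*; denitrification
and anammox from ²⁹N₂/³⁰N₂ by random isotope pairing
(D = P30/f², A = (P29 − 2((1−f)/f)P30)/f, reported in N-atom units); O₂
drawdown from optode series.

**Stoichiometric budgets.** Expected aerobic O₂ demand (0.5 × nitrite
oxidation, by electron balance), the nitrite→nitrate flux attributable to
anammox (c × anammox/2) and its fraction of measured oxidation, and the
share of N₂ production that disproportionation could supply
((2/3) × oxidation / N₂ production).

**Michaelis–Menten kinetics.** `MichaelisMenten(...).fit()` estimates
V = Vm·[S]/([S] + Km) with Wald uncertainties, adjusted R², and a one-sided
test of Km > 0 (saturation kinetics versus a flat response).

**Synthetic data.** Every input the pipeline reads can be generated with
known ground truth: ODZ-like profiles (secondary nitrite maximum ~2 µM,
heavy nitrate over light nitrite, rates of order 1–40 nM d⁻¹) via the
forward steady-state solver, tracer time courses on the 3-time-point ×
5-bottle design, and kinetics ladders spanning 0.5–13.8 µM.

## Worked example

```python
from odzrates import (default_scenario, generate_profile_dataset, invert_profile,
                      generate_tracer_experiment, nitrite_oxidation_rate,
                      n2_pairing_rates, fit_linear_rate, o2_budget)

sc = default_scenario(seed=11)                      # synthetic ODZ scenario
profile, truth = generate_profile_dataset(sc)       # noisy profile + ground truth
print(invert_profile(profile, sc.transport).summary())
```

```
Inverse isotope model — per-depth NNLS inversion
================================================================
depths (interior): 58   solved: 58   flagged: 0
kz = 1.6 m²/d   w = -0.2 m/d   c = 0.16
disproportionation column: included
----------------------------------------------------------------
process      peak rate    at depth     mean rate
f_nar         77.11 nM/d       545 m      13.24 nM/d
f_nir         19.86 nM/d       590 m       3.63 nM/d
f_amx          5.19 nM/d       590 m       1.07 nM/d
f_dis         42.16 nM/d       545 m       4.92 nM/d
----------------------------------------------------------------
median residual norm: 0.000439 nM/d
```

The recovered disproportionation profile peaks at 42 nM-NO₃⁻ d⁻¹ against a
true peak of 36 — per-depth inversion of noisy measured profiles is exact
only in the noise-free limit (the test suite quantifies both).  The same
scenario's tracer incubation yields

```python
tc = generate_tracer_experiment(sc)
ox = nitrite_oxidation_rate(tc["no3_15_ex_nM"])
denit, amx = n2_pairing_rates(tc["n2_29_ex_nM"], tc["n2_30_ex_nM"])
print(ox.rate, ox.se)          # 31.2 ± 0.7 nM-N/d (truth: 31.7)
o2_budget(ox, fit_linear_rate(tc["o2_nM"])).classification
                               # 'O2-insufficient'
```

i.e. the measured O₂ consumption (10.1 nM d⁻¹) cannot support the expected
aerobic demand (15.6 nM d⁻¹) of the observed nitrite oxidation — the budget
signature of anaerobic nitrite oxidation.

A command-line front end wraps the same stages:

```sh
odzrates simulate --seed 3 --outdir sim
odzrates invert --profiles sim/profile.csv --config config.yaml
odzrates rates --timecourses sim/timecourses.csv --f-label 0.78
odzrates kinetics --table sim/kinetics.csv
odzrates budget --rates rates_out/incubation_rates.csv
```

## Layout

| module | contents |
| --- | --- |
| `odzrates.stoichiometry` | reaction network, fractionation, balance matrix |
| `odzrates.transport` | 1-D steady-state diffusion–advection, both directions |
| `odzrates.inversion` | per-depth NNLS model + results |
| `odzrates.incubation` | tracer rate estimators, isotope pairing, budgets |
| `odzrates.kinetics` | Michaelis–Menten model + results |
| `odzrates.simulate` | scenario configs and synthetic-data generators |
| `odzrates.io`, `odzrates.cli` | tables, YAML config, command line |

See `docs/methods.md` for the model equations, parameter defaults, the
design of the synthetic scenarios and known limitations.
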