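# Methods

## The balance model

The model describes the anoxic core of an oxygen-deficient zone as a 1-D
vertical column at steady state.  Five dissolved pools are tracked —
¹⁴NH₄⁺, ¹⁴NO₂⁻, ¹⁴NO₃⁻, ¹⁵NO₂⁻ and ¹⁵NO₃⁻ — and each obeys

    K_z C''(z) − w C'(z) + R(z) = 0,

with depth z positive downward (m), eddy diffusivity K_z (m² d⁻¹),
advection w (m d⁻¹, positive downward, so upwelling is w < 0) and net
biochemical rate R (production positive).  Horizontal transport is not
represented; the model is meant for the interior of the column, not the
surface layer.

Four processes generate R:

| process | symbol | units | NH₄⁺ | NO₂⁻ | NO₃⁻ | N₂-N |
| --- | --- | --- | --- | --- | --- | --- |
| nitrate reduction | F_Nar | nM-N d⁻¹ | +0.07 | +1 | −1 | — |
| denitrification | F_Nir | nM-N d⁻¹ | +0.11 | −1 | — | +1 |
| anammox | F_Amx | nM-N d⁻¹ (NH₄⁺ consumed) | −1 | −(1+c) | +c | +2 |
| disproportionation | F_Dis | nM-NO₃⁻ d⁻¹ (NO₃⁻ produced) | — | −5/3 | +1 | +2/3 |

The 0.11 and 0.07 terms are ammonium released by remineralisation of
organic matter oxidised during nitrite and nitrate reduction; c = 0.16 is
the nitrate side branch of anammox.  The 5/3 and 2/3 factors are the
disproportionation stoichiometry (5 NO₂⁻ → 3 NO₃⁻ + 2 N₂-N); their
difference is 1 by nitrogen conservation and the constructor enforces it.
H⁺ and H₂O are not modelled (no pH state).  The resulting invariant,
checked over random rate vectors,

    R_NH4 + R_NO2 + R_NO3 + N₂-production = 0.11 F_Nir + 0.07 F_Nar,

says that all nitrogen not re-supplied by remineralisation is conserved
between the pools and the N₂ sink.

The ¹⁵N rows repeat the ¹⁴N structure with each flux divided by its
fractionation factor α and multiplied by the ¹⁵N/¹⁴N ratio of its substrate
pool.  Fractionation factors are configured as enrichment factors ε (‰),
α = 1 + ε/1000, with defaults ε_Nar = 25, ε_Nir = 12, ε_Amx = 16 and
ε_Nxr = −13 (nitrite oxidation fractionates inversely).  These are
representative literature magnitudes, not measured constants, and are
deliberately user-configurable.  The disproportionation branches are tied
by default: its nitrate branch fractionates like nitrite oxidation
(α_Dis = α_Nxr), its N₂ branch like denitrification (α_DisN2 = α_Nir).
δ¹⁵N ↔ ratio conversion uses r = r_std (1 + δ/1000) with
r_std = 0.0036765 (atmospheric N₂); r_std is configurable.

## Discretisation and the inverse direction

Both directions use central second-order differences on a uniform grid
(order ≈ 2 verified by manufactured solutions).  Measured profiles on
irregular grids are regridded by monotone piecewise-cubic (PCHIP)
interpolation; optional Savitzky–Golay pre-smoothing exists but is off by
default — differentiating noisy field data amplifies noise by
K_z √6 σ_C / h², and that risk should be a conscious choice.  The forward
solver uses Dirichlet boundaries taken from the first and last grid values,
solves the three ¹⁴N pools independently (tridiagonal systems) and then the
two ¹⁵N pools as one coupled sparse linear system, since their sources are
linear in the ¹⁵N concentrations once the ¹⁴N solution is known.  Negative
solution values are reported and flagged, never clipped.  The advective
term keeps the cell Péclet number |w| h / K_z ≤ 2 in all shipped scenarios;
beyond that, central differences oscillate.

The inversion applies the same stencils to the measured profiles
(R = w C' − K_z C''), builds the 5×4 matrix from the local measured isotope
ratios, and solves each interior depth independently by nonnegative least
squares (`scipy.optimize.nnls`, the same active-set method as MATLAB's
`lsqnonneg`).  Using identical stencils in both directions makes the
noise-free round trip exact to solver precision — a property the tests rely
on.  Depths where nitrite or nitrate falls below a configurable floor
(default 0.01 µM) have undefined isotope ratios; their rates are reported
missing and flagged rather than imputed.  No cross-depth regularisation or
smoothing of R is applied: each depth stands alone.  Removing the
disproportionation column (`include_disproportionation=False`) gives the
canonical three-process model; being nested, its residual norm can never
beat the four-process fit, which the tests assert depth by depth.

## Tracer incubation estimators

Rates are OLS slopes of product versus time; replicate bottles enter as
separate observations.  The default design is the field protocol: one
killed bottle at day 0 (a regression point, not a subtracted blank), two at
0.5 d and two at 1 d; O₂ is monitored at 32 time points.  Nitrite oxidation
divides the excess-¹⁵NO₃⁻ slope by the atom fraction
f = added ¹⁵NO₂⁻ / (ambient + added), treating natural abundance as
negligible against tracer additions of several µM.  Isotope pairing assumes
random pairing within the nitrite pool: denitrification N₂ distributes
2f(1−f) : f² between masses 29 and 30, anammox N₂ takes one nitrite atom
(labelled with probability f) and one unlabelled ammonium atom.  Hence
D = P30/f² and A = (P29 − 2((1−f)/f)P30)/f in N₂ units, ×2 for N atoms —
formulas validated against a direct Monte-Carlo pairing simulation.  A
negative anammox estimate is reported as such and marked non-significant.
Anammox rates are reported per N atom (the ×2 convention is explicit in
`n2_pairing_rates` and can be undone by halving).  An estimate is
"significant" when |rate| > 1.96 × SE; the multiplier is a convention, and
`RateEstimate.ci()` gives exact t-based intervals (df = n − 2) when
coverage matters.

The budget logic: aerobic nitrite oxidation consumes 0.5 mol O₂ per mol
NO₂⁻ (two electrons to O₂, four electrons per O₂); a measured O₂
consumption that falls short of that demand by more than its standard error
classifies the oxidation as O₂-insufficient, i.e. anaerobic.  The anammox
nitrate branch is c × A/2; the disproportionation ceiling on N₂ production
is (2/3) × oxidation rate, reported uncapped with a flag when it exceeds
the measured N₂ production.

## Michaelis–Menten fits

Bounded nonlinear least squares (trust-region reflective) on
V = Vm S/(S + Km), started at Vm₀ = max rate and Km₀ = the level nearest
half-max.  Uncertainties are Wald (from the curvature at the optimum);
Km > 0 is a one-sided t test (df = n − 2) at α = 0.05.  Wald intervals on
Km are approximate for small n and near-flat responses — the saturated
regime is exactly where the test is designed to fail to reject, and a
regression test holds that line.  Optional inverse-variance weighting by
the per-level rate SEs is available but off by default (those SEs are
themselves estimated from n = 3–5 regressions).  Adjusted R² uses p = 2
parameters; a fit with r²_adj outside [0, 1] or a failed convergence is
flagged degenerate, not raised.

## The synthetic scenarios

The default profile scenario is a 60-depth uniform grid from 80 to 965 m
(h = 15 m), K_z = 1.6 m² d⁻¹, w = −0.2 m d⁻¹ (upwelling), boundaries
NH₄⁺ 0.1/0.15 µM, NO₂⁻ 0.1/0.05 µM, NO₃⁻ 28/38 µM, δ¹⁵N-NO₂⁻ = −14 ‰ and
δ¹⁵N-NO₃⁻ = +14 ‰ at both ends.  Rate fields are sums of Gaussian bumps
with two activity maxima (360 m and 550 m); disproportionation peaks at
36 nM-NO₃⁻ d⁻¹, nitrate reduction components shadow the sink stoichiometry
plus a small surplus that sustains a secondary nitrite maximum of ~2 µM
near the top of the core, and anammox shadows the remineralised ammonium
supply it depends on.  Two constraints shaped these choices and are worth
stating because they are physics, not tuning:

* a steady 1-D column with K_z of order 1 m² d⁻¹ cannot import tens of
  nM d⁻¹ of column-integrated nitrogen loss by diffusion alone — the
  gradients required would drive pools negative.  Bulk supply must ride on
  the advective term, hence the upwelling velocity and the nitrate
  increase toward the lower boundary;
* each process keeps a smaller component at the other maximum.  Per-depth
  NNLS has a one-sided clipping bias of order the noise level for any
  process whose competitor is exactly zero at its peak (the estimate
  cannot err negative, and the covariance drags the co-varying rates
  down).  With no process pinned at zero inside the core, ensemble peak
  biases stay below ~3–5%.

Measurement noise is multiplicative log-normal on total concentrations
(default sd 1%) and additive Gaussian on δ¹⁵N (default 0.2 ‰), applied to
the measurement-style table and converted back to pools — the structure of
real concentration and isotope-ratio errors.  Peak-recovery error is
quantified as the recovered rate at the depth of the true peak, relative to
the true peak; the maximum over depth of a noisy profile would carry a
max-statistic upward bias of ~15% for the weaker processes and is not used
as a metric.

The tracer scenario uses a true nitrite-oxidation rate of 31.7 nM d⁻¹,
denitrification 16 and anammox 6 nM-N d⁻¹, a 7.24 µM label addition to a
2 µM ambient pool (f ≈ 0.78), and 0.5 nM Gaussian noise per bottle.  The
kinetics scenario uses Km = 1.2 µM, Vm = 25 nM d⁻¹ on seven levels from 0.5
to 13.8 µM with 5% multiplicative noise.

What the generators do **not** emulate: correlated (instrument-drift)
errors, non-steady-state dynamics, horizontal advection, bottle effects or
time-variable rates within an incubation, and real stations' O₂
microstructure.  Passing the recovery tests therefore demonstrates the
estimators are correct and well-calibrated under the stated error model,
not that field profiles of comparable noise will invert this cleanly.

## Numerical conventions

Concentrations are carried in µM, rates in nM d⁻¹, with a single 10³
conversion where transport meets biochemistry.  All generators are pure
functions of their scenario (seed included); identical scenarios give
identical bytes.  Problem sizes in the tests and the verification script —
100 seeds for the noisy-recovery ensemble, 1000 replicates for CI coverage,
200 kinetics fits, 10⁶ Monte-Carlo pairings, 500 NNLS oracle systems — were
chosen to keep the statistical checks' own uncertainty well inside the
asserted margins.

## Known limitations

* Denitrification and the N₂ branch of disproportionation are isotopically
  identical by construction (α_DisN2 = α_Nir); separating F_Nir from F_Dis
  rests on the nitrate-production signature and is the weakest-identified
  direction of the inversion.  Expect the widest errors on F_Nir.
* No uncertainty propagation from profile noise to inverted rates is
  built in; the synthetic ensemble is the intended way to judge it.
* The Michaelis–Menten module fits saturation kinetics only; O₂-response
  curves that are non-monotonic (inhibition) should be summarised, not
  fitted.
* Isotope ratios use pool concentrations as given; at concentrations near
  the floor the ratio, and hence the whole depth, is discarded rather than
  modelled.
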