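"""Rate estimation from 15N tracer incubation time courses.

A rate experiment incubates a set of bottles amended with 15NO2- tracer and
terminates them in a time series (typically one bottle at day zero, two at
half a day and two at one day).  Rates come from ordinary least-squares
slopes of product concentration versus time:

* nitrite oxidation — slope of excess 15NO3-, divided by the 15N atom
  fraction of the nitrite pool;
* denitrification and anammox — isotope pairing of the 29N2 and 30N2
  production slopes;
* oxygen production/consumption — slope of O2 (optode series, many points).

The module also carries the stoichiometric budget arguments that interpret
those rates: the aerobic O2 demand a nitrite-oxidation rate would impose,
the nitrite-to-nitrate flux attributable to anammox, and the share of N2
production explainable by nitrite disproportionation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TracerTimeCourse",
    "RateEstimate",
    "fit_linear_rate",
    "nitrite_oxidation_rate",
    "n2_pairing_rates",
    "o2_budget",
    "anammox_coupled_oxidation",
    "disproportionation_n2_share",
    "atom_fraction",
]

ANALYTES = ("no3_15_ex_nM", "n2_29_ex_nM", "n2_30_ex_nM", "o2_nM")

#: critical multiplier for the "error bar excludes zero" significance rule
Z_CRIT = 1.96


def atom_fraction(added_15no2_uM: float, ambient_no2_uM: float) -> float:
    """15N atom fraction of the nitrite pool after tracer addition.

    Assumes the natural 15N abundance of the ambient pool is negligible
    against the added label (natural abundance ~0.37% vs. additions of
    0.5–13.8 µM to ~2 µM ambient pools).
    """
    if added_15no2_uM <= 0:
        raise ValueError("added tracer concentration must be > 0")
    if ambient_no2_uM < 0:
        raise ValueError("ambient concentration must be >= 0")
    return added_15no2_uM / (ambient_no2_uM + added_15no2_uM)


@dataclass
class TracerTimeCourse:
    """One incubation series: analyte concentration per bottle versus time.

    ``f_label`` is the 15N atom fraction of the labelled substrate pool;
    required (in (0, 1]) for 15N-derived analytes, ignored for O2.
    Replicate bottles at the same time point are separate observations.
    """

    times: np.ndarray
    values: np.ndarray
    analyte: str
    f_label: float | None = None
    bottle_ids: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}; expected one of {ANALYTES}")
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.values))):
            raise ValueError("times and values must be finite")
        if np.unique(self.times).size < 3:
            raise ValueError(
                f"need >= 3 distinct time points, got {np.unique(self.times).size}"
            )
        if self.analyte != "o2_nM":
            if self.f_label is None or not (0.0 < self.f_label <= 1.0):
                raise ValueError(
                    f"f_label must be in (0, 1] for analyte {self.analyte!r}, got {self.f_label!r}"
                )

    @property
    def n(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class RateEstimate:
    """A slope-derived rate (nM d-1 or nM-N d-1) with its standard error."""

    rate: float
    se: float
    n: int
    significant_override: bool | None = None

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("standard error must be >= 0")

    @property
    def significant(self) -> bool:
        """True when the error bar (Z_CRIT x se) excludes zero; estimators
        may override (e.g. a negative pairing-derived anammox rate)."""
        if self.significant_override is not None:
            return self.significant_override
        return abs(self.rate) > Z_CRIT * self.se

    def scaled(self, k: float) -> "RateEstimate":
        return RateEstimate(rate=k * self.rate, se=abs(k) * self.se, n=self.n)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """t-based confidence interval on the rate (df = n - 2)."""
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        return self.rate - tcrit * self.se, self.rate + tcrit * self.se


def fit_linear_rate(tc: TracerTimeCourse) -> RateEstimate:
    """OLS slope of analyte concentration versus time and its standard error."""
    if np.unique(tc.times).size < 2:
        raise ValueError("all time points identical; slope undefined")
    res = stats.linregress(tc.times, tc.values)
    se = 0.0 if not np.isfinite(res.stderr) else float(res.stderr)
    # exact fit through > 2 points: linregress reports ~0 already, keep as is
    return RateEstimate(rate=float(res.slope), se=se, n=tc.n)


def nitrite_oxidation_rate(tc: TracerTimeCourse) -> RateEstimate:
    """Nitrite oxidation rate from an excess-15NO3- time course, nM-N d-1.

    The measured slope only tracks labelled molecules; dividing by the atom
    fraction of the nitrite pool scales it back to the full pool.
    """
    if tc.analyte != "no3_15_ex_nM":
        raise ValueError(f"expected a 15NO3- excess course, got analyte {tc.analyte!r}")
    if not tc.f_label or tc.f_label <= 0:
        raise ValueError("f_label must be > 0")
    return fit_linear_rate(tc).scaled(1.0 / tc.f_label)


def n2_pairing_rates(
    tc29: TracerTimeCourse, tc30: TracerTimeCourse
) -> tuple[RateEstimate, RateEstimate]:
    """Denitrification and anammox rates from 29N2/30N2 courses, nM-N d-1.

    Classical random isotope pairing with nitrite atom fraction f: a
    denitrification N2 draws both atoms from the nitrite pool, so its
    29N2:30N2 production follows the binomial 2f(1-f) : f^2; an anammox N2
    pairs one nitrite atom (labelled with probability f) with one ammonium
    atom (unlabelled), contributing to 29N2 only.  Hence, with P29 and P30
    the production slopes in nM-N2 d-1:

        denitrification N2 = P30 / f^2
        anammox N2         = (P29 - 2 (1-f)/f * P30) / f

    Both are converted to N-atom units (x2).  A negative anammox estimate
    is reported as such (it cannot be significant), never truncated.
    """
    if tc29.analyte != "n2_29_ex_nM" or tc30.analyte != "n2_30_ex_nM":
        raise ValueError("expected (29N2, 30N2) excess courses in that order")
    if not np.array_equal(np.sort(tc29.times), np.sort(tc30.times)):
        raise ValueError("29N2 and 30N2 courses must share time points")
    f = tc29.f_label
    if f is None or f <= 0:
        raise ValueError("f_label must be > 0")
    if tc30.f_label is not None and not np.isclose(tc30.f_label, f):
        raise ValueError("29N2 and 30N2 courses disagree on f_label")
    p29 = fit_linear_rate(tc29)
    p30 = fit_linear_rate(tc30)
    denit = p30.scaled(2.0 / f**2)
    # anammox combines two independent slopes; propagate their SEs in quadrature
    amx_rate = 2.0 * (p29.rate - 2.0 * (1.0 - f) / f * p30.rate) / f
    amx_se = 2.0 / f * float(np.hypot(p29.se, 2.0 * (1.0 - f) / f * p30.se))
    amx = RateEstimate(rate=amx_rate, se=amx_se, n=p29.n,
                       significant_override=False if amx_rate < 0 else None)
    return denit, amx


@dataclass(frozen=True)
class O2Budget:
    expected_o2_demand: float
    o2_consumption: float
    classification: str  # 'aerobic-consistent' | 'O2-insufficient'


def o2_budget(no2_ox: RateEstimate, o2_rate: RateEstimate) -> O2Budget:
    """Would the measured O2 drawdown support aerobic nitrite oxidation?

    Aerobic oxidation transfers 2 electrons per NO2- to O2 (4 e- per O2),
    so the expected O2 demand is half the nitrite-oxidation rate.  The
    measured O2 rate is signed (+ production, - consumption); the budget is
    classified O2-insufficient when consumption plus one standard error
    still falls short of the demand.
    """
    expected = 0.5 * no2_ox.rate
    consumption = max(0.0, -o2_rate.rate)
    if consumption + o2_rate.se < expected:
        label = "O2-insufficient"
    else:
        label = "aerobic-consistent"
    return O2Budget(expected_o2_demand=expected, o2_consumption=consumption, classification=label)


@dataclass(frozen=True)
class AnammoxOxidation:
    no3_production: float
    fraction_of_oxidation: float
    defined: bool


def anammox_coupled_oxidation(
    amx: RateEstimate, no2_ox_rate: float, c: float = 0.16
) -> AnammoxOxidation:
    """Nitrite-to-nitrate flux attributable to anammox and its share of a
    measured nitrite-oxidation rate.

    ``amx`` is in N2 N-atom units; ammonium consumption is amx/2 and the
    nitrate side branch produces c x amx/2.  The share is undefined
    (flagged) when the supplied oxidation rate is zero.
    """
    if c < 0:
        raise ValueError("c must be >= 0")
    no3_prod = c * amx.rate / 2.0
    if no2_ox_rate == 0:
        return AnammoxOxidation(no3_production=no3_prod, fraction_of_oxidation=np.nan, defined=False)
    return AnammoxOxidation(
        no3_production=no3_prod,
        fraction_of_oxidation=no3_prod / no2_ox_rate,
        defined=True,
    )


@dataclass(frozen=True)
class DisproportionationShare:
    share: float
    defined: bool
    exceeds_unity: bool


def disproportionation_n2_share(
    no2_ox: RateEstimate, n2_prod: RateEstimate
) -> DisproportionationShare:
    """Fraction of measured N2 production attributable to disproportionation.

    If all measured nitrite oxidation (as NO3- production) ran through
    disproportionation it would co-produce 2/3 as much N2-N; the share is
    that ceiling over the measured N2 production rate.  Reported uncapped
    with a flag when > 1; undefined when N2 production is not positive
    (unless the oxidation rate is zero too, in which case the share is 0).
    """
    if n2_prod.rate <= 0:
        if no2_ox.rate == 0:
            return DisproportionationShare(share=0.0, defined=True, exceeds_unity=False)
        return DisproportionationShare(share=np.nan, defined=False, exceeds_unity=False)
    share = (2.0 / 3.0) * no2_ox.rate / n2_prod.rate
    return DisproportionationShare(share=share, defined=True, exceeds_unity=share > 1.0)
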