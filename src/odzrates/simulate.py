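"""Synthetic data with known ground truth for every pipeline stage.

Emulates the three kinds of observation the analysis consumes:

* ODZ-like depth profiles — Gaussian process-rate fields pushed through the
  forward steady-state transport model, yielding an anoxic-core scenario
  with a secondary nitrite maximum of a couple of µM, heavy nitrate / light
  nitrite isotope structure, and rates of order 1–40 nM d-1;
* tracer incubation time courses — linear expected trajectories from true
  rates (15NO3- slope = rate x f; 29/30N2 slopes from the random-pairing
  formulas) plus Gaussian measurement noise, on the 3-time-point /
  5-bottle design;
* kinetics experiments — Michaelis–Menten rates at a ladder of substrate
  levels plus multiplicative noise.

All generators are pure functions of the scenario (which includes the
seed): the same scenario yields identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .incubation import TracerTimeCourse, atom_fraction
from .kinetics import KineticsExperiment, michaelis_menten
from .stoichiometry import FractionationSet, StoichiometryParams
from .transport import DepthProfile, TransportParams, solve_steady_state

__all__ = [
    "GaussianBump",
    "ScenarioConfig",
    "default_scenario",
    "generate_profile_dataset",
    "generate_tracer_experiment",
    "generate_kinetics_experiment",
]


@dataclass(frozen=True)
class GaussianBump:
    """One Gaussian component of a rate field: peak (nM d-1), depth (m), width (m)."""

    peak: float
    depth: float
    width: float

    def __post_init__(self):
        if self.peak < 0 or self.width <= 0:
            raise ValueError("GaussianBump requires peak >= 0 and width > 0")

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return self.peak * np.exp(-((np.asarray(z, dtype=float) - self.depth) ** 2)
                                  / (2.0 * self.width**2))


def _eval_field(components, z):
    out = np.zeros_like(np.asarray(z, dtype=float))
    for comp in components:
        out += comp(z)
    return out


@dataclass
class ScenarioConfig:
    """Everything a synthetic run needs, ground truth included.

    The default numbers describe the study conditions the package is built
    around: an anoxic ODZ core sampled on a 60-depth uniform grid, nitrite
    disproportionation peaking at 36 nM-NO3- d-1, a secondary nitrite
    maximum near 2 µM, heavy nitrate (delta15N ~ +14 permil) over light
    nitrite (~ -14 permil), a 3-time-point / 5-bottle tracer design with a
    7.24 µM label addition to a ~2 µM ambient pool, and kinetics levels
    spanning 0.5–13.8 µM.
    """

    seed: int = 0
    # --- profile scenario -------------------------------------------------
    z_top: float = 80.0
    z_bottom: float = 965.0
    n_depths: int = 60
    kz: float = 1.6           # m^2 d-1
    w: float = -0.2           # m d-1, positive downward (negative: upwelling)
    rate_fields: dict = field(default_factory=dict)
    boundary: dict = field(default_factory=dict)
    conc_noise_sd: float = 0.01     # multiplicative (log-normal) on totals
    delta_noise_sd: float = 0.2     # additive, permil, on delta15N
    # --- tracer scenario --------------------------------------------------
    no2_ox_rate: float = 31.7       # nM-N d-1
    denit_rate: float = 16.0        # nM-N d-1 (N atom units)
    amx_rate: float = 6.0           # nM-N d-1 (N atom units)
    o2_rate: float = -10.0          # nM d-1 (negative = consumption)
    added_15no2_uM: float = 7.24
    ambient_no2_uM: float = 2.0
    times_d: tuple = (0.0, 0.5, 0.5, 1.0, 1.0)   # 3 time points, 5 bottles
    n_o2_points: int = 32
    tracer_noise_sd_nM: float = 0.5
    # --- kinetics scenario ------------------------------------------------
    km_uM: float = 1.2
    vm_nM_d: float = 25.0
    kinetics_levels_uM: tuple = (0.5, 1.0, 2.0, 4.0, 7.0, 10.0, 13.8)
    kinetics_noise_frac: float = 0.05

    def __post_init__(self):
        if not self.rate_fields:
            self.rate_fields = _default_rate_fields()
        if not self.boundary:
            self.boundary = _default_boundary()
        if self.n_depths < 5:
            raise ValueError("need >= 5 depths")
        for name, comps in self.rate_fields.items():
            for c in comps:
                if c.peak < 0:
                    raise ValueError(f"negative peak in rate field {name}")

    @property
    def z(self) -> np.ndarray:
        return np.linspace(self.z_top, self.z_bottom, self.n_depths)

    @property
    def transport(self) -> TransportParams:
        return TransportParams(kz=self.kz, w=self.w)

    @property
    def f_label(self) -> float:
        return atom_fraction(self.added_15no2_uM, self.ambient_no2_uM)

    def true_rates(self) -> pd.DataFrame:
        """Ground-truth process-rate fields on the grid (nM d-1)."""
        z = self.z
        return pd.DataFrame(
            {
                "depth_m": z,
                "f_nir": _eval_field(self.rate_fields["f_nir"], z),
                "f_nar": _eval_field(self.rate_fields["f_nar"], z),
                "f_amx": _eval_field(self.rate_fields["f_amx"], z),
                "f_dis": _eval_field(self.rate_fields["f_dis"], z),
            }
        )


def _default_rate_fields() -> dict:
    """Gaussian rate fields of the default anoxic-core scenario.

    Two activity maxima: a shallow one near 360 m dominated by
    denitrification and a deep one near 550 m dominated by
    disproportionation, each process carrying a smaller component at the
    other maximum (ODZ rate profiles overlap; no process switches off
    abruptly inside the core).  Nitrate reduction is the nitrite source
    feeding all three sinks; its components shadow the sink stoichiometry
    (5/3 per disproportionation NO3-, 1 per denitrified N, 1+c per anammox
    NH4+) plus a small surplus that sustains the secondary nitrite maximum,
    and anammox likewise shadows the remineralised ammonium supply
    (0.11 f_nir + 0.07 f_nar) it depends on.  A source field that strayed
    far from its sinks would force multi-µM pool excursions that the weak
    vertical mixing of an ODZ core cannot balance at steady state; bulk
    nitrogen import is carried by the upwelling term instead.
    """
    return {
        "f_nir": [GaussianBump(15.0, 360.0, 45.0), GaussianBump(6.0, 550.0, 50.0)],
        "f_amx": [GaussianBump(2.8, 360.0, 45.0), GaussianBump(5.0, 550.0, 40.0)],
        "f_dis": [GaussianBump(36.0, 550.0, 40.0), GaussianBump(6.0, 360.0, 50.0)],
        "f_nar": [
            GaussianBump(60.0, 550.0, 40.0),   # shadows 5/3 x f_dis (deep)
            GaussianBump(15.0, 360.0, 45.0),   # shadows f_nir (shallow)
            GaussianBump(3.25, 360.0, 45.0),   # shadows (1+c) x f_amx (shallow)
            GaussianBump(5.8, 550.0, 40.0),    # shadows (1+c) x f_amx (deep)
            GaussianBump(6.0, 550.0, 50.0),    # shadows f_nir background (deep)
            GaussianBump(10.0, 360.0, 50.0),   # shadows 5/3 x f_dis background
            GaussianBump(3.0, 470.0, 55.0),    # surplus: secondary NO2- maximum
        ],
    }


def _default_boundary() -> dict:
    return {
        "nh4": (0.1, 0.15),
        "no2": (0.1, 0.05),
        "no3": (28.0, 38.0),
        "d15n_no2": (-14.0, -14.0),
        "d15n_no3": (14.0, 14.0),
    }


def default_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """The frozen default scenario with a chosen seed (fields overridable)."""
    return replace(ScenarioConfig(seed=seed), **overrides)


def generate_profile_dataset(
    sc: ScenarioConfig,
    stoich: StoichiometryParams | None = None,
    alphas: FractionationSet | None = None,
) -> tuple[DepthProfile, pd.DataFrame]:
    """Forward-model a depth profile (with measurement noise) plus its truth.

    Returns ``(profile, true_rates)``.  The zero-noise profile satisfies the
    discrete steady-state balance exactly; with noise, totals get
    multiplicative log-normal errors and the delta15N columns additive
    Gaussian errors, mimicking concentration and isotope-ratio measurement
    uncertainty.  Rate fields that drive any pool negative raise an error
    naming the offending depth.
    """
    if stoich is None:
        stoich = StoichiometryParams()
    if alphas is None:
        alphas = FractionationSet()
    truth = sc.true_rates()
    F = truth[["f_nir", "f_nar", "f_amx", "f_dis"]].to_numpy()
    clean = solve_steady_state(
        F, sc.boundary, sc.z, sc.transport, stoich=stoich, alphas=alphas
    )
    if clean.negative_values:
        for name in ("conc_14nh4", "conc_14no2", "conc_14no3", "conc_15no2", "conc_15no3"):
            v = getattr(clean, name)
            if np.any(v < 0):
                zbad = clean.z[int(np.argmin(v))]
                raise ValueError(
                    f"rate fields drive {name} negative (min {v.min():.3g} µM "
                    f"at depth {zbad:g} m); rescale the scenario"
                )
    if sc.conc_noise_sd == 0 and sc.delta_noise_sd == 0:
        return clean, truth

    rng = np.random.default_rng(sc.seed)
    table = clean.to_dataframe()
    n = len(table)
    for col in ("nh4_uM", "no2_uM", "no3_uM"):
        table[col] = table[col] * np.exp(rng.normal(0.0, sc.conc_noise_sd, size=n))
    for col in ("d15n_no2_permil", "d15n_no3_permil"):
        table[col] = table[col] + rng.normal(0.0, sc.delta_noise_sd, size=n)
    noisy = DepthProfile.from_totals_and_delta(
        z=table["depth_m"].to_numpy(),
        nh4_uM=table["nh4_uM"].to_numpy(),
        no2_uM=table["no2_uM"].to_numpy(),
        no3_uM=table["no3_uM"].to_numpy(),
        d15n_no2_permil=table["d15n_no2_permil"].to_numpy(),
        d15n_no3_permil=table["d15n_no3_permil"].to_numpy(),
        r_std=clean.r_std,
    )
    return noisy, truth


def pairing_slopes(denit_rate: float, amx_rate: float, f: float) -> tuple[float, float]:
    """Expected 29N2 and 30N2 production slopes (nM-N2 d-1) from true rates.

    Random pairing in the nitrite pool at atom fraction f: denitrification
    N2 (denit_rate/2 in N2 units) splits 2f(1-f) : f^2 between masses 29
    and 30; anammox N2 (amx_rate/2) takes one nitrite atom, labelled with
    probability f, and an unlabelled ammonium atom, so a fraction f is
    29N2.  Only excess above natural abundance is tracked, so the 28N2
    channels drop out.
    """
    if not (0.0 < f <= 1.0):
        raise ValueError("f must be in (0, 1]")
    d_n2 = denit_rate / 2.0
    a_n2 = amx_rate / 2.0
    p30 = d_n2 * f**2
    p29 = d_n2 * 2.0 * f * (1.0 - f) + a_n2 * f
    return p29, p30


def generate_tracer_experiment(sc: ScenarioConfig) -> dict[str, TracerTimeCourse]:
    """Simulate one incubation set: 15NO3-, 29N2, 30N2 and O2 courses.

    Expected trajectories are linear in time; Gaussian noise of
    ``tracer_noise_sd_nM`` is added to every bottle except the day-zero
    killed control of the 15N analytes (included as a regression point at
    its expected value of zero plus noise as well — the control is measured
    like any other bottle).
    """
    f = sc.f_label
    rng = np.random.default_rng(sc.seed)
    times = np.asarray(sc.times_d, dtype=float)
    p29, p30 = pairing_slopes(sc.denit_rate, sc.amx_rate, f)
    slopes = {
        "no3_15_ex_nM": sc.no2_ox_rate * f,
        "n2_29_ex_nM": p29,
        "n2_30_ex_nM": p30,
    }
    expected_floor = {k: s * times for k, s in slopes.items()}
    for k, exp_vals in expected_floor.items():
        if np.any(exp_vals < 0):
            raise ValueError(f"negative expected concentration in {k}")
    out = {}
    for analyte, s in slopes.items():
        values = s * times
        if sc.tracer_noise_sd_nM > 0:
            values = values + rng.normal(0.0, sc.tracer_noise_sd_nM, size=times.size)
        out[analyte] = TracerTimeCourse(times=times, values=values, analyte=analyte, f_label=f)
    t_o2 = np.linspace(0.0, times.max(), sc.n_o2_points)
    o2_start = 50.0  # nM, trace O2 level in a He-flushed exetainer
    o2_vals = o2_start + sc.o2_rate * t_o2
    if sc.tracer_noise_sd_nM > 0:
        o2_vals = o2_vals + rng.normal(0.0, sc.tracer_noise_sd_nM, size=t_o2.size)
    out["o2_nM"] = TracerTimeCourse(times=t_o2, values=o2_vals, analyte="o2_nM")
    return out


def generate_kinetics_experiment(sc: ScenarioConfig) -> KineticsExperiment:
    """Michaelis–Menten rates at the scenario's substrate levels plus noise."""
    levels = np.asarray(sc.kinetics_levels_uM, dtype=float)
    if np.unique(levels).size < 4:
        raise ValueError("need >= 4 distinct kinetics levels")
    rng = np.random.default_rng(sc.seed)
    rates = michaelis_menten(levels, sc.vm_nM_d, sc.km_uM)
    if sc.kinetics_noise_frac > 0:
        rates = rates * (1.0 + rng.normal(0.0, sc.kinetics_noise_frac, size=levels.size))
    return KineticsExperiment(substrate_conc=levels, rates=rates, substrate="no2")
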