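"""Reaction network, stoichiometry and isotope fractionation of the anoxic
nitrogen cycle.

The model resolves four processes in the anoxic core of an oxygen-deficient
zone (ODZ):

* nitrate reduction to nitrite (``f_nar``),
* denitrification sensu stricto, nitrite reduction to N2 (``f_nir``),
* anammox, expressed as ammonium consumed (``f_amx``), with a minor
  nitrite-to-nitrate side branch scaled by the factor ``c``,
* nitrite disproportionation, 5 NO2- + 2 H+ -> N2 + 3 NO3- + H2O,
  expressed as nitrate produced (``f_dis``).

At each depth these map linearly onto the net biochemical production or
consumption of the five tracked pools (14NH4+, 14NO2-, 14NO3-, 15NO2-,
15NO3-).  The 15N rows carry kinetic fractionation factors (alpha) and the
local 15N/14N ratios of the nitrite and nitrate pools.

All process and net rates are in nM-N d-1, except ``f_dis`` which is in
nM-NO3- d-1 and is converted internally through the 5/3 (nitrite consumed)
and 2/3 (N2-N produced) stoichiometric factors of the disproportionation
reaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "R_STD_AIR",
    "StoichiometryParams",
    "FractionationSet",
    "ProcessRates",
    "NetRates",
    "IsotopeState",
    "delta_to_ratio",
    "ratio_to_delta",
    "build_stoichiometry_matrix",
    "forward_rates",
    "n2_production",
]

#: 15N/14N isotope ratio of atmospheric N2, the delta15N reference standard.
R_STD_AIR = 0.0036765

#: Row order of the balance matrix (net-rate components).
ROW_ORDER = ("r_14nh4", "r_14no2", "r_14no3", "r_15no2", "r_15no3")

#: Column order of the balance matrix (process rates).
COLUMN_ORDER = ("f_nir", "f_nar", "f_amx", "f_dis")


def delta_to_ratio(delta_permil, r_std: float = R_STD_AIR):
    """Convert delta15N (per mil vs. AIR) to a 15N/14N isotope ratio."""
    return r_std * (1.0 + np.asarray(delta_permil, dtype=float) / 1000.0)


def ratio_to_delta(ratio, r_std: float = R_STD_AIR):
    """Convert a 15N/14N isotope ratio to delta15N (per mil vs. AIR)."""
    return (np.asarray(ratio, dtype=float) / r_std - 1.0) * 1000.0


@dataclass(frozen=True)
class StoichiometryParams:
    """Fixed stoichiometric coefficients of the reaction network.

    Parameters
    ----------
    c : float
        Moles of nitrate produced per mole of ammonium consumed by anammox
        (the nitrite-oxidizing side branch of the anammox reaction).
    remin_nir : float
        Ammonium released by organic-matter remineralisation per N
        denitrified (nitrite -> N2).
    remin_nar : float
        Ammonium released per N of nitrate reduced to nitrite.
    dis_no2_per_no3 : float
        Nitrite consumed per nitrate produced by disproportionation (5/3).
    dis_n2_per_no3 : float
        N2-N produced per nitrate produced by disproportionation (2/3).
    """

    c: float = 0.16
    remin_nir: float = 0.11
    remin_nar: float = 0.07
    dis_no2_per_no3: float = 5.0 / 3.0
    dis_n2_per_no3: float = 2.0 / 3.0

    def __post_init__(self):
        for name in ("c", "remin_nir", "remin_nar", "dis_no2_per_no3", "dis_n2_per_no3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"StoichiometryParams.{name} must be finite and >= 0, got {v!r}")
        # N conservation within the disproportionation reaction:
        # every nitrite N ends up either in nitrate or in N2.
        if abs(self.dis_no2_per_no3 - self.dis_n2_per_no3 - 1.0) > 1e-12:
            raise ValueError(
                "dis_no2_per_no3 - dis_n2_per_no3 must equal 1 (N conservation), "
                f"got {self.dis_no2_per_no3} - {self.dis_n2_per_no3}"
            )


def _eps_to_alpha(eps_permil: float) -> float:
    return 1.0 + eps_permil / 1000.0


@dataclass(frozen=True)
class FractionationSet:
    """Kinetic isotope fractionation factors (alpha = 14k/15k), near 1.

    ``alpha_dis`` defaults to the nitrite-oxidation factor (the nitrate
    produced by disproportionation carries the nitrite-oxidoreductase
    fractionation) and ``alpha_dis_n2`` defaults to the denitrification
    factor (the N2 branch runs through nitrite reductase).
    """

    alpha_nar: float = _eps_to_alpha(25.0)
    alpha_nir: float = _eps_to_alpha(12.0)
    alpha_amx: float = _eps_to_alpha(16.0)
    alpha_nxr_amx: float = _eps_to_alpha(-13.0)
    alpha_dis: float = _eps_to_alpha(-13.0)
    alpha_dis_n2: float = _eps_to_alpha(12.0)

    def __post_init__(self):
        for name in (
            "alpha_nar",
            "alpha_nir",
            "alpha_amx",
            "alpha_nxr_amx",
            "alpha_dis",
            "alpha_dis_n2",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"FractionationSet.{name} must be finite and > 0, got {v!r}")

    @classmethod
    def from_epsilons(
        cls,
        eps_nar: float = 25.0,
        eps_nir: float = 12.0,
        eps_amx: float = 16.0,
        eps_nxr: float = -13.0,
        eps_dis: float | None = None,
        eps_dis_n2: float | None = None,
        eps_nxr_amx: float | None = None,
    ) -> "FractionationSet":
        """Build from enrichment factors epsilon (per mil), alpha = 1 + eps/1000.

        ``eps_dis`` and ``eps_nxr_amx`` default to ``eps_nxr`` (nitrate
        production from nitrite fractionates like canonical nitrite
        oxidation, which is inverse, eps < 0); ``eps_dis_n2`` defaults to
        ``eps_nir``.
        """
        if eps_dis is None:
            eps_dis = eps_nxr
        if eps_dis_n2 is None:
            eps_dis_n2 = eps_nir
        if eps_nxr_amx is None:
            eps_nxr_amx = eps_nxr
        return cls(
            alpha_nar=_eps_to_alpha(eps_nar),
            alpha_nir=_eps_to_alpha(eps_nir),
            alpha_amx=_eps_to_alpha(eps_amx),
            alpha_nxr_amx=_eps_to_alpha(eps_nxr_amx),
            alpha_dis=_eps_to_alpha(eps_dis),
            alpha_dis_n2=_eps_to_alpha(eps_dis_n2),
        )

    @classmethod
    def no_fractionation(cls) -> "FractionationSet":
        """All alpha = 1 (useful limit: 15N behaves exactly like 14N)."""
        return cls(1.0, 1.0, 1.0, 1.0, 1.0, 1.0)


@dataclass(frozen=True)
class ProcessRates:
    """The four process rates at one depth.

    ``f_nar``, ``f_nir``, ``f_amx`` in nM-N d-1; ``f_dis`` in nM-NO3- d-1
    (nitrate produced by disproportionation).
    """

    f_nar: float = 0.0
    f_nir: float = 0.0
    f_amx: float = 0.0
    f_dis: float = 0.0

    def __post_init__(self):
        for name in ("f_nar", "f_nir", "f_amx", "f_dis"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"ProcessRates.{name} must be finite and >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        """Rates in the matrix column order (f_nir, f_nar, f_amx, f_dis)."""
        return np.array([self.f_nir, self.f_nar, self.f_amx, self.f_dis], dtype=float)

    @classmethod
    def from_array(cls, x) -> "ProcessRates":
        x = np.asarray(x, dtype=float)
        if x.shape != (4,):
            raise ValueError(f"expected 4 rates (f_nir, f_nar, f_amx, f_dis), got shape {x.shape}")
        return cls(f_nir=x[0], f_nar=x[1], f_amx=x[2], f_dis=x[3])


@dataclass(frozen=True)
class NetRates:
    """Net biochemical production (+) / consumption (-) of the five pools, nM d-1."""

    r_14nh4: float
    r_14no2: float
    r_14no3: float
    r_15no2: float
    r_15no3: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.r_14nh4, self.r_14no2, self.r_14no3, self.r_15no2, self.r_15no3],
            dtype=float,
        )

    @classmethod
    def from_array(cls, x) -> "NetRates":
        x = np.asarray(x, dtype=float)
        if x.shape != (5,):
            raise ValueError(f"expected 5 net rates, got shape {x.shape}")
        return cls(*x)


@dataclass(frozen=True)
class IsotopeState:
    """Local 15N/14N ratios of the nitrite and nitrate pools.

    ``r_std`` is the reference ratio used for delta conversion (AIR).
    """

    r_no2: float
    r_no3: float
    r_std: float = R_STD_AIR

    def __post_init__(self):
        for name in ("r_no2", "r_no3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"IsotopeState.{name} must be finite and >= 0, got {v!r}")
        if not np.isfinite(self.r_std) or self.r_std <= 0:
            raise ValueError(f"IsotopeState.r_std must be finite and > 0, got {self.r_std!r}")


def build_stoichiometry_matrix(
    stoich: StoichiometryParams,
    alphas: FractionationSet,
    iso: IsotopeState,
) -> np.ndarray:
    """Assemble the 5x4 balance matrix A mapping process rates to net rates.

    Rows follow ``ROW_ORDER`` (14NH4+, 14NO2-, 14NO3-, 15NO2-, 15NO3-),
    columns follow ``COLUMN_ORDER`` (f_nir, f_nar, f_amx, f_dis).  The 14N
    rows are the network stoichiometry; the 15N rows divide each flux by its
    fractionation factor and multiply by the 15N/14N ratio of its substrate
    pool.
    """
    c = stoich.c
    r2, r3 = iso.r_no2, iso.r_no3
    A = np.zeros((5, 4), dtype=float)
    # 14NH4+: remineralisation source minus anammox consumption
    A[0] = (stoich.remin_nir, stoich.remin_nar, -1.0, 0.0)
    # 14NO2-
    A[1] = (-1.0, 1.0, -(1.0 + c), -stoich.dis_no2_per_no3)
    # 14NO3-
    A[2] = (0.0, -1.0, c, 1.0)
    # 15NO2-
    A[3] = (
        -r2 / alphas.alpha_nir,
        r3 / alphas.alpha_nar,
        -r2 / alphas.alpha_amx - c * r2 / alphas.alpha_nxr_amx,
        -r2 / alphas.alpha_dis - stoich.dis_n2_per_no3 * r2 / alphas.alpha_dis_n2,
    )
    # 15NO3-
    A[4] = (0.0, -r3 / alphas.alpha_nar, c * r2 / alphas.alpha_nxr_amx, r2 / alphas.alpha_dis)
    return A


def forward_rates(F: ProcessRates, A: np.ndarray) -> NetRates:
    """Evaluate the network in the forward direction: NetRates = A @ F."""
    A = np.asarray(A, dtype=float)
    if A.shape != (5, 4):
        raise ValueError(f"balance matrix must be 5x4, got shape {A.shape}")
    return NetRates.from_array(A @ F.as_array())


def n2_production(
    F: ProcessRates, stoich: StoichiometryParams | None = None
) -> tuple[float, dict[str, float]]:
    """Total N2 production in nM-N d-1 and its per-pathway breakdown.

    Denitrification contributes one N per nitrite reduced (f_nir is already
    in N units); anammox pairs one ammonium N with one nitrite N (2 N per
    ammonium consumed); disproportionation yields 2 N2-N per 3 nitrate
    produced.
    """
    if stoich is None:
        stoich = StoichiometryParams()
    parts = {
        "denitrification": F.f_nir,
        "anammox": 2.0 * F.f_amx,
        "disproportionation": stoich.dis_n2_per_no3 * F.f_dis,
    }
    return sum(parts.values()), parts
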