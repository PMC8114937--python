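"""One-dimensional steady-state vertical transport of nitrogen pools.

Depth ``z`` is positive downward (m); the advection velocity ``w`` is
positive downward as well.  At steady state every pool obeys

    kz * C''(z) - w * C'(z) + R(z) = 0,

where ``R`` is the net biochemical production (+) or consumption (-) rate.
The module provides both directions on a uniform grid with central
second-order stencils:

* :func:`net_rate_from_profile` — differentiate measured profiles to get
  ``R(z) = w C' - kz C''`` at interior nodes (the inverse direction);
* :func:`solve_steady_state` — solve the Dirichlet boundary-value problem
  for the five pools given process-rate fields (the forward direction).

Concentrations are carried in µM and rates in nM d-1 (the 10^3 conversion
happens at this boundary); depths in m, kz in m^2 d-1, w in m d-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.interpolate import PchipInterpolator
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .stoichiometry import (
    FractionationSet,
    R_STD_AIR,
    StoichiometryParams,
    delta_to_ratio,
    ratio_to_delta,
)

__all__ = [
    "UM_TO_NM",
    "TransportParams",
    "DepthProfile",
    "transport_rate_uM",
    "net_rate_from_profile",
    "solve_steady_state",
]

#: µM -> nM conversion applied where concentrations meet rates.
UM_TO_NM = 1.0e3

POOLS = ("conc_14nh4", "conc_14no2", "conc_14no3", "conc_15no2", "conc_15no3")


@dataclass(frozen=True)
class TransportParams:
    """Vertical eddy diffusivity kz (m^2 d-1) and advection w (m d-1, + down)."""

    kz: float
    w: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.kz) or self.kz <= 0:
            raise ValueError(f"TransportParams.kz must be finite and > 0, got {self.kz!r}")
        if not np.isfinite(self.w):
            raise ValueError(f"TransportParams.w must be finite, got {self.w!r}")


@dataclass
class DepthProfile:
    """Gridded concentrations of the five modelled pools (µM) versus depth (m).

    The isotope pools are stored explicitly; use :meth:`from_totals_and_delta`
    to build one from the measured quantities (total concentrations plus
    delta15N of nitrite and nitrate) and :meth:`to_dataframe` to get back a
    measurement-style table.  ``negative_values`` flags profiles produced by
    the forward solver that undershoot zero (reported, never clipped).
    """

    z: np.ndarray
    conc_14nh4: np.ndarray
    conc_14no2: np.ndarray
    conc_14no3: np.ndarray
    conc_15no2: np.ndarray
    conc_15no3: np.ndarray
    o2: np.ndarray | None = None
    r_std: float = R_STD_AIR
    negative_values: bool = False

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        for name in POOLS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.o2 is not None:
            self.o2 = np.asarray(self.o2, dtype=float)
        n = self.z.size
        if n < 5:
            raise ValueError(f"depth grid needs >= 5 points, got {n}")
        if np.unique(self.z).size != n:
            dup = self.z[pd.Index(self.z).duplicated()][0]
            raise ValueError(f"duplicate depth {dup} m in grid")
        if not np.all(np.diff(self.z) > 0):
            raise ValueError("depth grid must be strictly increasing")
        for name in POOLS:
            v = getattr(self, name)
            if v.shape != self.z.shape:
                raise ValueError(f"{name} length {v.size} != grid length {n}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")
            if not self.negative_values and np.any(v < 0):
                raise ValueError(f"{name} contains negative concentrations")

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_totals_and_delta(
        cls,
        z,
        nh4_uM,
        no2_uM,
        no3_uM,
        d15n_no2_permil,
        d15n_no3_permil,
        o2_uM=None,
        r_std: float = R_STD_AIR,
    ) -> "DepthProfile":
        """Split measured totals into 14N/15N pools using delta15N.

        A pool with ratio r = r_std (1 + delta/1000) has 15N fraction
        r/(1+r).  Ammonium carries no isotope column; its (tiny) natural
        15N content is irrelevant to the balance equations and the total is
        used as the 14N pool.
        """
        no2 = np.asarray(no2_uM, dtype=float)
        no3 = np.asarray(no3_uM, dtype=float)
        r2 = delta_to_ratio(d15n_no2_permil, r_std)
        r3 = delta_to_ratio(d15n_no3_permil, r_std)
        return cls(
            z=z,
            conc_14nh4=np.asarray(nh4_uM, dtype=float),
            conc_14no2=no2 / (1.0 + r2),
            conc_14no3=no3 / (1.0 + r3),
            conc_15no2=no2 * r2 / (1.0 + r2),
            conc_15no3=no3 * r3 / (1.0 + r3),
            o2=o2_uM,
            r_std=r_std,
        )

    # -- derived quantities ----------------------------------------------
    def isotope_ratios(self, conc_floor_uM: float = 0.0):
        """Per-depth 15N/14N ratios of nitrite and nitrate.

        Depths where the 14N pool is at or below ``conc_floor_uM`` get NaN
        (ratio undefined at vanishing concentration).
        """
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(self.conc_14no2 > conc_floor_uM, self.conc_15no2 / self.conc_14no2, np.nan)
            r3 = np.where(self.conc_14no3 > conc_floor_uM, self.conc_15no3 / self.conc_14no3, np.nan)
        return r2, r3

    def to_dataframe(self) -> pd.DataFrame:
        """Measurement-style table: totals (µM) plus delta15N (per mil)."""
        no2 = self.conc_14no2 + self.conc_15no2
        no3 = self.conc_14no3 + self.conc_15no3
        r2, r3 = self.isotope_ratios()
        out = pd.DataFrame(
            {
                "depth_m": self.z,
                "nh4_uM": self.conc_14nh4,
                "no2_uM": no2,
                "no3_uM": no3,
                "d15n_no2_permil": ratio_to_delta(r2, self.r_std),
                "d15n_no3_permil": ratio_to_delta(r3, self.r_std),
            }
        )
        if self.o2 is not None:
            out["o2_uM"] = self.o2
        return out

    @property
    def spacing(self) -> float:
        h = np.diff(self.z)
        if not np.allclose(h, h[0], rtol=1e-8, atol=1e-12):
            raise ValueError(
                f"grid spacing is non-uniform (min {h.min():g} m, max {h.max():g} m); "
                "regrid before differencing"
            )
        return float(h[0])

    def regridded(self, n: int | None = None) -> "DepthProfile":
        """Monotone piecewise-cubic (PCHIP) regrid onto a uniform grid."""
        if n is None:
            n = self.z.size
        zu = np.linspace(self.z[0], self.z[-1], n)
        kw = {name: PchipInterpolator(self.z, getattr(self, name))(zu) for name in POOLS}
        o2 = PchipInterpolator(self.z, self.o2)(zu) if self.o2 is not None else None
        # interpolation can overshoot 0 by rounding; clamp the eps-level dust
        for name, v in kw.items():
            kw[name] = np.where((v < 0) & (v > -1e-12), 0.0, v)
        return DepthProfile(z=zu, o2=o2, r_std=self.r_std, **kw)

    def smoothed(self, window: int = 5, polyorder: int = 2) -> "DepthProfile":
        """Savitzky-Golay pre-smoothing of all pools (optional, off by default
        in every pipeline entry point: differentiating noisy field data is
        the user's call)."""
        kw = {name: savgol_filter(getattr(self, name), window, polyorder) for name in POOLS}
        return DepthProfile(z=self.z.copy(), o2=self.o2, r_std=self.r_std,
                            negative_values=True, **kw)


def _transport_matrix(n: int, h: float, t: TransportParams) -> sp.csr_matrix:
    """Interior-node operator T with (T C)_i = kz C'' - w C' (central stencils).

    Shape (n-2, n): columns span the full grid so boundary values multiply
    through naturally.
    """
    kz, w = t.kz, t.w
    lower = kz / h**2 + w / (2.0 * h)
    diag = -2.0 * kz / h**2
    upper = kz / h**2 - w / (2.0 * h)
    rows, cols, vals = [], [], []
    for i in range(n - 2):
        rows += [i, i, i]
        cols += [i, i + 1, i + 2]
        vals += [lower, diag, upper]
    return sp.csr_matrix((vals, (rows, cols)), shape=(n - 2, n))


def transport_rate_uM(z: np.ndarray, conc_uM: np.ndarray, t: TransportParams) -> np.ndarray:
    """R = w C' - kz C'' at interior nodes, in µM d-1 (raw operator)."""
    z = np.asarray(z, dtype=float)
    c = np.asarray(conc_uM, dtype=float)
    h = np.diff(z)
    if not np.allclose(h, h[0], rtol=1e-8, atol=1e-12):
        raise ValueError(
            f"grid spacing is non-uniform (min {h.min():g} m, max {h.max():g} m); "
            "regrid before differencing"
        )
    h = h[0]
    d1 = (c[2:] - c[:-2]) / (2.0 * h)
    d2 = (c[2:] - 2.0 * c[1:-1] + c[:-2]) / h**2
    return t.w * d1 - t.kz * d2


def net_rate_from_profile(
    profile: DepthProfile,
    t: TransportParams,
    regrid: bool = False,
    smooth: bool = False,
) -> pd.DataFrame:
    """Net biochemical rates R (nM d-1) of the five pools at interior depths.

    Rearranges the steady-state balance: whatever divergence of the
    diffusive-advective flux is not explained by transport must be
    biochemical production or consumption.  Endpoints are excluded (no
    centered stencil there).
    """
    h = np.diff(profile.z)
    if not np.allclose(h, h[0], rtol=1e-8, atol=1e-12):
        if not regrid:
            raise ValueError(
                f"grid spacing is non-uniform (min {h.min():g} m, max {h.max():g} m); "
                "pass regrid=True to interpolate onto a uniform grid"
            )
        profile = profile.regridded()
    if smooth:
        profile = profile.smoothed()
    out = {"depth_m": profile.z[1:-1]}
    for name, col in zip(POOLS, ("r_14nh4", "r_14no2", "r_14no3", "r_15no2", "r_15no3")):
        out[col] = UM_TO_NM * transport_rate_uM(profile.z, getattr(profile, name), t)
    return pd.DataFrame(out)


def _rate_fields(rate_fields, n: int) -> np.ndarray:
    """Normalise per-depth process rates to an (n, 4) array in column order."""
    if isinstance(rate_fields, pd.DataFrame):
        F = np.column_stack(
            [rate_fields[k].to_numpy(dtype=float) for k in ("f_nir", "f_nar", "f_amx", "f_dis")]
        )
    elif isinstance(rate_fields, dict):
        F = np.column_stack(
            [np.asarray(rate_fields[k], dtype=float) for k in ("f_nir", "f_nar", "f_amx", "f_dis")]
        )
    else:
        F = np.asarray(rate_fields, dtype=float)
    if F.shape != (n, 4):
        raise ValueError(f"rate fields must have shape ({n}, 4), got {F.shape}")
    if not np.all(np.isfinite(F)) or np.any(F < 0):
        raise ValueError("process rates must be finite and >= 0 everywhere")
    return F


def solve_steady_state(
    rate_fields,
    boundary: dict[str, tuple[float, float]],
    z,
    t: TransportParams,
    stoich: StoichiometryParams | None = None,
    alphas: FractionationSet | None = None,
    r_std: float = R_STD_AIR,
) -> DepthProfile:
    """Solve the five coupled steady-state boundary-value problems.

    Parameters
    ----------
    rate_fields : DataFrame, dict of arrays, or (n, 4) array
        Per-depth process rates in column order (f_nir, f_nar, f_amx,
        f_dis), nM d-1 (f_dis in nM-NO3- d-1), one row per grid node.
    boundary : dict
        Keys 'nh4', 'no2', 'no3' mapping to (top, bottom) total
        concentrations in µM, plus 'd15n_no2' and 'd15n_no3' mapping to
        (top, bottom) delta15N in per mil.
    z : array
        Uniform, strictly increasing depth grid (m), >= 5 points.

    The three 14N pools are independent tridiagonal solves (their sources
    depend only on the rate fields).  The two 15N pools are coupled — their
    sources are linear in the 15N concentrations once the 14N solution is
    known — and are solved as a single sparse linear system.  Negative
    concentrations anywhere are reported via ``negative_values`` and a
    warning, never clipped.
    """
    if stoich is None:
        stoich = StoichiometryParams()
    if alphas is None:
        alphas = FractionationSet()
    z = np.asarray(z, dtype=float)
    n = z.size
    if n < 5:
        raise ValueError(f"depth grid needs >= 5 points, got {n}")
    h = np.diff(z)
    if not np.allclose(h, h[0], rtol=1e-8, atol=1e-12):
        raise ValueError("solve_steady_state requires a uniform grid")
    h = float(h[0])
    F = _rate_fields(rate_fields, n)
    f_nir, f_nar, f_amx, f_dis = F.T

    for key in ("nh4", "no2", "no3", "d15n_no2", "d15n_no3"):
        if key not in boundary:
            raise ValueError(f"boundary condition '{key}' missing")
    for key in ("nh4", "no2", "no3"):
        lo, hi = boundary[key]
        if lo < 0 or hi < 0:
            raise ValueError(f"boundary concentration for '{key}' must be >= 0")

    # split boundary totals into isotope pools
    b = {}
    for sp_name, dkey in (("no2", "d15n_no2"), ("no3", "d15n_no3")):
        r = delta_to_ratio(np.asarray(boundary[dkey], dtype=float), r_std)
        tot = np.asarray(boundary[sp_name], dtype=float)
        b[f"14{sp_name}"] = tot / (1.0 + r)
        b[f"15{sp_name}"] = tot * r / (1.0 + r)
    b["14nh4"] = np.asarray(boundary["nh4"], dtype=float)

    T = _transport_matrix(n, h, t)  # (n-2, n), acts on full-grid vectors

    def dirichlet_solve(source_uM_d: np.ndarray, c_top: float, c_bot: float) -> np.ndarray:
        """Solve T C = -source on interior with fixed endpoint values."""
        Ti = T[:, 1:-1]
        rhs = -source_uM_d.copy()
        rhs -= T[:, 0].toarray().ravel() * c_top
        rhs -= T[:, -1].toarray().ravel() * c_bot
        interior = spsolve(Ti.tocsc(), rhs)
        return np.concatenate([[c_top], interior, [c_bot]])

    c = stoich.c
    # 14N sources (nM d-1 -> µM d-1)
    src = {
        "14nh4": (stoich.remin_nir * f_nir + stoich.remin_nar * f_nar - f_amx) / UM_TO_NM,
        "14no2": (-f_nir + f_nar - (1.0 + c) * f_amx - stoich.dis_no2_per_no3 * f_dis) / UM_TO_NM,
        "14no3": (-f_nar + c * f_amx + f_dis) / UM_TO_NM,
    }
    sol = {k: dirichlet_solve(v[1:-1], *b[k]) for k, v in src.items()}

    # 15N system: R15no2 = a*C15no2 + b2*C15no3; R15no3 = d*C15no2 + e*C15no3
    # where the coefficients divide the per-depth fluxes by alpha and the
    # local 14N pool (ratio = C15/C14).  Units: 1/d after the µM conversion.
    c14no2 = sol["14no2"]
    c14no3 = sol["14no3"]
    if np.any(c14no2 <= 0) or np.any(c14no3 <= 0):
        bad = z[np.where((c14no2 <= 0) | (c14no3 <= 0))[0][0]]
        raise ValueError(
            f"14N nitrite/nitrate solution non-positive at depth {bad:g} m; "
            "isotope ratios undefined — adjust rates or boundaries"
        )
    no2_sink = (
        f_nir / alphas.alpha_nir
        + f_amx / alphas.alpha_amx
        + c * f_amx / alphas.alpha_nxr_amx
        + f_dis / alphas.alpha_dis
        + stoich.dis_n2_per_no3 * f_dis / alphas.alpha_dis_n2
    )
    a_c = -no2_sink / UM_TO_NM / c14no2
    b_c = (f_nar / alphas.alpha_nar) / UM_TO_NM / c14no3
    d_c = (c * f_amx / alphas.alpha_nxr_amx + f_dis / alphas.alpha_dis) / UM_TO_NM / c14no2
    e_c = -(f_nar / alphas.alpha_nar) / UM_TO_NM / c14no3

    Ti = T[:, 1:-1]
    m = n - 2

    def diag_int(v):
        return sp.diags(v[1:-1])

    M = sp.bmat(
        [
            [Ti + diag_int(a_c), diag_int(b_c)],
            [diag_int(d_c), Ti + diag_int(e_c)],
        ],
        format="csc",
    )
    rhs = np.concatenate(
        [
            -T[:, 0].toarray().ravel() * b["15no2"][0] - T[:, -1].toarray().ravel() * b["15no2"][1],
            -T[:, 0].toarray().ravel() * b["15no3"][0] - T[:, -1].toarray().ravel() * b["15no3"][1],
        ]
    )
    x = spsolve(M, rhs)
    c15no2 = np.concatenate([[b["15no2"][0]], x[:m], [b["15no2"][1]]])
    c15no3 = np.concatenate([[b["15no3"][0]], x[m:], [b["15no3"][1]]])

    pools = {
        "conc_14nh4": sol["14nh4"],
        "conc_14no2": c14no2,
        "conc_14no3": c14no3,
        "conc_15no2": c15no2,
        "conc_15no3": c15no3,
    }
    negative = any(np.any(v < 0) for v in pools.values())
    if negative:
        worst = min(float(v.min()) for v in pools.values())
        warnings.warn(
            f"steady-state solution undershoots zero (min {worst:.3g} µM); "
            "values reported unclipped",
            RuntimeWarning,
            stacklevel=2,
        )
    return DepthProfile(z=z.copy(), r_std=r_std, negative_values=negative, **pools)
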