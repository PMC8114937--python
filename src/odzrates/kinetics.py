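"""Michaelis–Menten kinetics of nitrite oxidation.

Fits V = Vm [S] / ([S] + Km) to rate-versus-substrate experiments (nitrite
or oxygen response curves) by bounded nonlinear least squares, and tests
whether the half-saturation constant Km is significantly larger than zero —
the distinction between genuine saturation kinetics and a rate that is flat
over the tested range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "KineticsExperiment",
    "MichaelisMenten",
    "MichaelisMentenResults",
    "fit_michaelis_menten",
    "michaelis_menten",
]


def michaelis_menten(s, vm, km):
    """The saturation rate law V = Vm s / (s + Km)."""
    s = np.asarray(s, dtype=float)
    return vm * s / (s + km)


@dataclass
class KineticsExperiment:
    """Rate measurements across substrate levels (one curve).

    substrate_conc in µM, rates and rate_se in nM d-1.
    """

    substrate_conc: np.ndarray
    rates: np.ndarray
    rate_se: np.ndarray | None = None
    substrate: str = "no2"

    def __post_init__(self):
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rate_se is not None:
            self.rate_se = np.asarray(self.rate_se, dtype=float)
            if self.rate_se.shape != self.rates.shape:
                raise ValueError("rate_se must match rates in length")
            if np.any(self.rate_se < 0):
                raise ValueError("rate_se must be >= 0")
        if self.substrate_conc.shape != self.rates.shape:
            raise ValueError("substrate_conc and rates must have equal length")
        if np.unique(self.substrate_conc).size < 4:
            raise ValueError(
                f"need >= 4 distinct substrate levels, got {np.unique(self.substrate_conc).size}"
            )
        if np.any(self.substrate_conc < 0):
            raise ValueError("substrate concentrations must be >= 0")


@dataclass
class MichaelisMenten:
    """Model object: fit() returns :class:`MichaelisMentenResults`.

    ``weighted`` switches on inverse-variance weighting from ``rate_se``
    (default off; the replicate SEs of slope-derived rates are themselves
    noisy at n of a few).
    """

    experiment: KineticsExperiment
    weighted: bool = False
    alpha: float = 0.05

    def fit(self) -> "MichaelisMentenResults":
        ex = self.experiment
        s, v = ex.substrate_conc, ex.rates
        vm0 = float(np.max(v)) if np.max(v) > 0 else 1.0
        # start Km at the level closest to half-maximal response
        km0 = float(s[np.argmin(np.abs(v - vm0 / 2.0))])
        if km0 <= 0:
            km0 = float(np.median(s[s > 0])) if np.any(s > 0) else 1.0
        sigma = None
        if self.weighted and ex.rate_se is not None and np.all(ex.rate_se > 0):
            sigma = ex.rate_se
        try:
            popt, pcov = curve_fit(
                michaelis_menten,
                s,
                v,
                p0=(vm0, km0),
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                sigma=sigma,
                absolute_sigma=False,
                maxfev=20000,
            )
            converged = np.all(np.isfinite(popt)) and np.all(np.isfinite(np.diag(pcov)))
        except RuntimeError:
            popt, pcov, converged = (np.nan, np.nan), np.full((2, 2), np.nan), False
        return MichaelisMentenResults(model=self, popt=np.asarray(popt, dtype=float),
                                      pcov=np.asarray(pcov, dtype=float), converged=bool(converged))


@dataclass
class MichaelisMentenResults:
    """Fitted Vm, Km with Wald uncertainties and the Km > 0 call."""

    model: MichaelisMenten
    popt: np.ndarray
    pcov: np.ndarray
    converged: bool

    @property
    def vm(self) -> float:
        return float(self.popt[0])

    @property
    def km(self) -> float:
        return float(self.popt[1])

    @property
    def vm_se(self) -> float:
        return float(np.sqrt(self.pcov[0, 0]))

    @property
    def km_se(self) -> float:
        return float(np.sqrt(self.pcov[1, 1]))

    @property
    def df_resid(self) -> int:
        return self.model.experiment.rates.size - 2

    @property
    def fittedvalues(self) -> np.ndarray:
        ex = self.model.experiment
        return michaelis_menten(ex.substrate_conc, *self.popt)

    @property
    def r2_adj(self) -> float:
        """Adjusted R^2 of the fitted curve; NaN when degenerate."""
        v = self.model.experiment.rates
        if not self.converged:
            return float("nan")
        ss_res = float(np.sum((v - self.fittedvalues) ** 2))
        ss_tot = float(np.sum((v - v.mean()) ** 2))
        n = v.size
        if ss_tot == 0 or n <= 3:
            return float("nan")
        return 1.0 - (ss_res / ss_tot) * (n - 1) / (n - 3)

    @property
    def degenerate(self) -> bool:
        r2 = self.r2_adj
        return (not self.converged) or (not np.isfinite(r2)) or r2 < 0 or r2 > 1

    def km_pvalue(self) -> float:
        """One-sided Wald p-value for Km > 0 (t distribution, df = n - 2)."""
        if not self.converged or self.km_se == 0 or not np.isfinite(self.km_se):
            return float("nan")
        tstat = self.km / self.km_se
        return float(stats.t.sf(tstat, self.df_resid))

    @property
    def km_significant(self) -> bool:
        p = self.km_pvalue()
        return bool(np.isfinite(p) and p < self.model.alpha)

    def summary(self) -> str:
        lines = [
            "Michaelis–Menten fit",
            "=" * 48,
            f"substrate: {self.model.experiment.substrate}   "
            f"levels: {self.model.experiment.rates.size}   converged: {self.converged}",
            f"Vm = {self.vm:.3g} ± {self.vm_se:.3g} nM/d",
            f"Km = {self.km:.3g} ± {self.km_se:.3g} µM",
            f"adjusted R² = {self.r2_adj:.4f}" if np.isfinite(self.r2_adj) else
            "adjusted R² = degenerate",
            f"Km > 0 (one-sided, α = {self.model.alpha:g}): "
            f"{'significant' if self.km_significant else 'not significant'} "
            f"(p = {self.km_pvalue():.3g})",
        ]
        return "\n".join(lines)


def fit_michaelis_menten(
    experiment: KineticsExperiment, weighted: bool = False, alpha: float = 0.05
) -> MichaelisMentenResults:
    """Functional entry point: fit the saturation curve in one call."""
    return MichaelisMenten(experiment=experiment, weighted=weighted, alpha=alpha).fit()
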