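"""Delimited-text I/O and run configuration.

Table formats (all plain CSV with unit-suffixed column names):

* profile:    depth_m, nh4_uM, no2_uM, no3_uM, d15n_no2_permil,
              d15n_no3_permil [, o2_uM]
* timecourse: time_d, bottle_id, analyte, value  (analyte one of
              no3_15_ex_nM | n2_29_ex_nM | n2_30_ex_nM | o2_nM)
* kinetics:   substrate_uM, rate_nM_d [, rate_se_nM_d]
* rates:      depth_m, f_nar, f_nir, f_amx, f_dis, residual_norm, flags

Run configuration is a single YAML file; every scientific parameter
(c, remineralisation terms, epsilons, kz, w, r_std, floors) is explicit in
the parsed config so no value enters a run silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .incubation import ANALYTES, TracerTimeCourse
from .kinetics import KineticsExperiment
from .stoichiometry import FractionationSet, R_STD_AIR, StoichiometryParams
from .transport import DepthProfile, TransportParams

__all__ = [
    "read_profile_table",
    "write_profile_table",
    "read_timecourse_table",
    "write_timecourse_table",
    "read_kinetics_table",
    "write_rate_table",
    "RunConfig",
    "load_config",
]

PROFILE_COLUMNS = (
    "depth_m",
    "nh4_uM",
    "no2_uM",
    "no3_uM",
    "d15n_no2_permil",
    "d15n_no3_permil",
)


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


def read_profile_table(path, r_std: float = R_STD_AIR) -> DepthProfile:
    """Read and validate a depth-profile table into a :class:`DepthProfile`."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, PROFILE_COLUMNS, path)
    z = df["depth_m"].to_numpy(dtype=float)
    dup = pd.Index(z).duplicated()
    if dup.any():
        row = int(np.where(dup)[0][0]) + 2  # 1-based + header
        raise ValueError(f"{path}: duplicated depth {z[dup][0]:g} m at row {row}")
    if not np.all(np.diff(z) > 0):
        row = int(np.where(np.diff(z) <= 0)[0][0]) + 3
        raise ValueError(f"{path}: depth not strictly increasing at row {row}")
    for col in ("nh4_uM", "no2_uM", "no3_uM"):
        v = df[col].to_numpy(dtype=float)
        if np.any(v < 0):
            row = int(np.where(v < 0)[0][0]) + 2
            raise ValueError(f"{path}: negative {col} at row {row}")
    return DepthProfile.from_totals_and_delta(
        z=z,
        nh4_uM=df["nh4_uM"].to_numpy(dtype=float),
        no2_uM=df["no2_uM"].to_numpy(dtype=float),
        no3_uM=df["no3_uM"].to_numpy(dtype=float),
        d15n_no2_permil=df["d15n_no2_permil"].to_numpy(dtype=float),
        d15n_no3_permil=df["d15n_no3_permil"].to_numpy(dtype=float),
        o2_uM=df["o2_uM"].to_numpy(dtype=float) if "o2_uM" in df.columns else None,
        r_std=r_std,
    )


def write_profile_table(profile: DepthProfile, path) -> None:
    profile.to_dataframe().to_csv(path, index=False)


def read_timecourse_table(path, f_label: float | None = None) -> dict[str, TracerTimeCourse]:
    """Read a time-course table, grouped into one course per analyte.

    ``f_label`` applies to all 15N-derived analytes (it is experiment
    metadata, carried in the run config rather than per row).
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("time_d", "bottle_id", "analyte", "value"), path)
    unknown = set(df["analyte"].unique()) - set(ANALYTES)
    if unknown:
        raise ValueError(f"{path}: unknown analyte label(s) {sorted(unknown)}")
    out = {}
    for analyte, grp in df.groupby("analyte", sort=False):
        out[str(analyte)] = TracerTimeCourse(
            times=grp["time_d"].to_numpy(dtype=float),
            values=grp["value"].to_numpy(dtype=float),
            analyte=str(analyte),
            f_label=None if analyte == "o2_nM" else f_label,
            bottle_ids=grp["bottle_id"].to_numpy(),
        )
    return out


def write_timecourse_table(courses: dict[str, TracerTimeCourse], path) -> None:
    rows = []
    for analyte, tc in courses.items():
        ids = tc.bottle_ids if tc.bottle_ids is not None else np.arange(tc.n)
        for t, v, b in zip(tc.times, tc.values, ids):
            rows.append({"time_d": t, "bottle_id": b, "analyte": analyte, "value": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_kinetics_table(path) -> KineticsExperiment:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("substrate_uM", "rate_nM_d"), path)
    se = df["rate_se_nM_d"].to_numpy(dtype=float) if "rate_se_nM_d" in df.columns else None
    return KineticsExperiment(
        substrate_conc=df["substrate_uM"].to_numpy(dtype=float),
        rates=df["rate_nM_d"].to_numpy(dtype=float),
        rate_se=se,
    )


def write_rate_table(rates: pd.DataFrame, path) -> None:
    rates.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Parsed run configuration: parameter blocks plus paths and seed."""

    stoich: StoichiometryParams = field(default_factory=StoichiometryParams)
    alphas: FractionationSet = field(default_factory=FractionationSet)
    transport: TransportParams | None = None
    r_std: float = R_STD_AIR
    conc_floor_uM: float = 0.01
    f_label: float | None = None
    seed: int | None = None
    outdir: Path = Path(".")

    def echo(self) -> dict:
        """Every scientific parameter of the run, for the manifest/log."""
        d = {
            "c": self.stoich.c,
            "remin_nir": self.stoich.remin_nir,
            "remin_nar": self.stoich.remin_nar,
            "r_std": self.r_std,
            "conc_floor_uM": self.conc_floor_uM,
            "f_label": self.f_label,
            "seed": self.seed,
        }
        for name in ("alpha_nar", "alpha_nir", "alpha_amx", "alpha_nxr_amx",
                     "alpha_dis", "alpha_dis_n2"):
            d[name] = getattr(self.alphas, name)
        if self.transport is not None:
            d["kz_m2_d"] = self.transport.kz
            d["w_m_d"] = self.transport.w
        return d


def load_config(path) -> RunConfig:
    """Load a YAML run configuration.

    Recognised blocks: ``stoichiometry`` (c, remin_nir, remin_nar),
    ``fractionation`` (eps_nar, eps_nir, eps_amx, eps_nxr, eps_dis,
    eps_dis_n2, eps_nxr_amx, in permil), ``transport`` (kz, w), and
    top-level r_std, conc_floor_uM, f_label, seed, outdir.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    stoich = StoichiometryParams(**raw.get("stoichiometry", {}))
    alphas = FractionationSet.from_epsilons(**raw.get("fractionation", {}))
    transport = TransportParams(**raw["transport"]) if "transport" in raw else None
    return RunConfig(
        stoich=stoich,
        alphas=alphas,
        transport=transport,
        r_std=float(raw.get("r_std", R_STD_AIR)),
        conc_floor_uM=float(raw.get("conc_floor_uM", 0.01)),
        f_label=raw.get("f_label"),
        seed=raw.get("seed"),
        outdir=Path(raw.get("outdir", ".")),
    )
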