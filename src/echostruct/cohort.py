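"""Simulate clinical-style cohort tables for exercising the statistics pipeline.

Marginals are truncated Gaussians at configurable per-group means/SDs.
An optional Gaussian-copula knob couples the microstructure measure (sic)
with diastolic pressure (dbp); everything else is drawn independently.
A fixed seed yields an identical table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from echostruct import conventional
from echostruct.sic import compute_msi


@dataclass(frozen=True)
class ColumnSpec:
    mean: float
    sd: float
    lo: float = -math.inf
    hi: float = math.inf

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if self.lo >= self.hi:
            raise ValueError("lo must be below hi")


@dataclass(frozen=True)
class GroupParams:
    n: int
    columns: dict
    p_female: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.p_female is not None and not 0 <= self.p_female <= 1:
            raise ValueError("p_female must lie in [0, 1]")


@dataclass(frozen=True)
class CohortParams:
    groups: dict
    corr_sic_dbp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        if not -1 < self.corr_sic_dbp < 1:
            raise ValueError("|corr_sic_dbp| must be < 1")


def truncated_normal_moments(mean: float, sd: float, lo: float, hi: float) -> tuple:
    """Closed-form (mean, sd) of a Gaussian truncated to [lo, hi]."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    m, v = sps.truncnorm.stats(a, b, loc=mean, scale=sd, moments="mv")
    return float(m), float(math.sqrt(v))


def _draw_column(spec: ColumnSpec, z: np.ndarray) -> np.ndarray:
    """Map standard-normal draws through the truncated-Gaussian marginal."""
    a = (spec.lo - spec.mean) / spec.sd
    b = (spec.hi - spec.mean) / spec.sd
    u = sps.norm.cdf(z)
    return sps.truncnorm.ppf(u, a, b, loc=spec.mean, scale=spec.sd)


def simulate_cohort(params: CohortParams) -> pd.DataFrame:
    """One row per subject; columns: id, group, sex (if configured) and every
    configured measurement column."""
    rng = np.random.default_rng(params.seed)
    frames = []
    next_id = 1
    for group_name in params.groups:  # insertion order: deterministic
        gp = params.groups[group_name]
        cols = {}
        col_names = list(gp.columns)
        rho = params.corr_sic_dbp
        coupled = rho != 0.0 and "sic" in col_names and "dbp" in col_names
        z = {name: rng.standard_normal(gp.n) for name in col_names}
        if coupled:
            # Gaussian copula: re-express dbp's latent normal as correlated with sic's
            z["dbp"] = rho * z["sic"] + math.sqrt(1 - rho**2) * z["dbp"]
        for name in col_names:
            cols[name] = _draw_column(gp.columns[name], z[name])
        if "sbp" in cols and "dbp" in cols:
            # enforce sbp > dbp (physiologic pulse pressure floor)
            cols["dbp"] = np.minimum(cols["dbp"], cols["sbp"] - 5.0)
        # fs is simulated as a marginal; lvsd follows from it when absent
        if "fs" in cols and "lvsd" not in cols and "lvdd" in cols:
            cols["lvsd"] = cols["lvdd"] * (1.0 - cols["fs"])
        df = pd.DataFrame(cols)
        df.insert(0, "group", group_name)
        df.insert(0, "id", np.arange(next_id, next_id + gp.n))
        if gp.p_female is not None:
            df["sex"] = np.where(rng.random(gp.n) < gp.p_female, "F", "M")
        next_id += gp.n
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def attach_derived(table: pd.DataFrame) -> pd.DataFrame:
    """Attach lvwt, rwt, map, lv_mass, edv/esv/ef, fs and msi columns by
    applying the conventional-measure operations row by row."""
    out = table.copy()
    if len(out) == 0:
        return out
    required = {"ivs", "pw", "lvdd", "lvsd", "sbp", "dbp", "sic"}
    missing = sorted(required - set(out.columns))
    if missing:
        raise KeyError(f"missing required columns: {', '.join(missing)}")
    derived = {k: [] for k in ("lvwt", "rwt", "map", "lv_mass", "edv", "esv", "ef", "fs", "msi")}
    for row in out.itertuples(index=False):
        wt = conventional.lvwt(row.ivs, row.pw)
        r = conventional.rwt(wt, row.lvdd)
        edv, esv, ef = conventional.teichholz_volumes_ef(row.lvdd, row.lvsd)
        derived["lvwt"].append(wt)
        derived["rwt"].append(r)
        derived["map"].append(conventional.mean_arterial_pressure(row.sbp, row.dbp))
        derived["lv_mass"].append(conventional.lv_mass_devereux(row.ivs, row.lvdd, row.pw))
        derived["edv"].append(edv)
        derived["esv"].append(esv)
        derived["ef"].append(ef)
        derived["fs"].append(conventional.fractional_shortening(row.lvdd, row.lvsd))
        derived["msi"].append(compute_msi(row.sic, r).msi)
    for k, v in derived.items():
        out[k] = v
    return out


def clinical_preset(
    n_control: int = 28,
    n_hypertensive: int = 30,
    corr_sic_dbp: float = 0.4,
    seed: int = 0,
) -> CohortParams:
    """Two-group human cohort at the published group means/SDs.

    Wall thickness is split evenly between septum and posterior wall
    (each SD/sqrt(2) so their sum carries the published SD); lvsd is derived
    from simulated fractional shortening.
    """

    def group(n, age, sbp, dbp, wt_sd, fs, eprime, sic, p_female):
        half_sd = wt_sd / math.sqrt(2.0)
        return GroupParams(
            n=n,
            p_female=p_female,
            columns={
                "age": ColumnSpec(*age, lo=18, hi=100),
                "sbp": ColumnSpec(*sbp, lo=80, hi=260),
                "dbp": ColumnSpec(*dbp, lo=40, hi=160),
                "ivs": ColumnSpec(0.9, half_sd, lo=0.4, hi=2.0),
                "pw": ColumnSpec(0.9, half_sd, lo=0.4, hi=2.0),
                "lvdd": ColumnSpec(4.0, 0.5, lo=2.5, hi=6.5),
                "fs": ColumnSpec(*fs, lo=0.05, hi=0.6),
                "e_prime": ColumnSpec(*eprime, lo=2, hi=30),
                "sic": ColumnSpec(*sic, lo=1.0 / 256.0, hi=1.0),
            },
        )

    control = group(
        n_control,
        age=(52, 9),
        sbp=(121, 9),
        dbp=(72, 9),
        wt_sd=0.2,
        fs=(0.28, 0.08),
        eprime=(13.2, 3.1),
        sic=(0.23, 0.11),
        p_female=0.56,
    )
    hyper = group(
        n_hypertensive,
        age=(54, 3),
        sbp=(142, 19),
        dbp=(85, 12),
        wt_sd=0.3,
        fs=(0.27, 0.15),
        eprime=(10.1, 2.8),
        sic=(0.31, 0.15),
        p_female=0.47,
    )
    # hypertensive walls are thicker: mean lvwt 1.9
    hyper_cols = dict(hyper.columns)
    hyper_cols["ivs"] = ColumnSpec(0.95, 0.3 / math.sqrt(2.0), lo=0.4, hi=2.0)
    hyper_cols["pw"] = ColumnSpec(0.95, 0.3 / math.sqrt(2.0), lo=0.4, hi=2.0)
    hyper = GroupParams(n=hyper.n, columns=hyper_cols, p_female=hyper.p_female)
    return CohortParams(
        groups={"control": control, "hypertensive": hyper},
        corr_sic_dbp=corr_sic_dbp,
        seed=seed,
    )


def murine_preset(seed: int = 0) -> CohortParams:
    """Three-group murine analogue (sham / debanded / banded) with severity-
    ordered microstructure means; group means are calibrated by this package,
    not published values."""

    def group(n, sic_mean, sic_sd, mass_mean, mass_sd):
        return GroupParams(
            n=n,
            columns={
                "sic": ColumnSpec(sic_mean, sic_sd, lo=1.0 / 256.0, hi=1.0),
                "rwt": ColumnSpec(0.45, 0.03, lo=0.1, hi=1.0),
                "lv_mass": ColumnSpec(mass_mean, mass_sd, lo=40, hi=300),
            },
        )

    return CohortParams(
        groups={
            "sham": group(3, 0.20, 0.03, 90, 10),
            "debanded": group(4, 0.28, 0.04, 95, 12),
            "banded": group(3, 0.36, 0.05, 140, 15),
        },
        seed=seed,
    )
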