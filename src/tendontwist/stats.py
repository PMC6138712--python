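"""Sensitivity analysis (+/- one standard deviation in twist, CSA and
collagen stiffness) and the supporting one-way analysis of variance.

Each factor is perturbed one-at-a-time about the subject's baseline and
the rupture load re-measured; factors are then ranked by their mean
absolute percent effect. The ANOVA is the classical between/within
mean-square ratio with an F-distribution p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .geometry import TendonMesh, build_mesh, ffd_scale_csa, label_compartments, label_subtendons
from .fiber import fiber_field_from_twist
from .synthetic import ANATOMICAL_AREA_FRACTIONS
from .experiments import LoadSplit, run_rupture
from .solver import SolverConfig

__all__ = [
    "SensitivityDesign",
    "AnovaResult",
    "run_sensitivity",
    "rank_factors",
    "anova_oneway",
]

FACTORS = ("csa", "c5", "twist")


@dataclass(frozen=True)
class SensitivityDesign:
    """One-at-a-time +/- sigma perturbation design.

    Sigmas default to the synthetic population's own spread: CSA and
    stiffness standard deviations as reported for cadaver cohorts, twist
    sigma of 14 degrees around the 37 degree anatomical mean.
    """

    csa_sigma_fraction: float = 15.0 / 70.0  # sigma/mean of CSA
    c5_sigma: float = 250.0                  # MPa
    twist_sigma: float = 14.0                # degrees
    factors: tuple = FACTORS

    def __post_init__(self):
        if min(self.csa_sigma_fraction, self.c5_sigma, self.twist_sigma) < 0:
            raise ValueError("sigmas must be non-negative")
        unknown = set(self.factors) - set(FACTORS)
        if unknown:
            raise ValueError(f"unknown factors {unknown}")


@dataclass
class AnovaResult:
    """Classical one-way ANOVA summary (iterable as (F, p))."""

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.f_statistic, self.p_value))

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SS": [self.ss_between, self.ss_within],
                "df": [self.df_between, self.df_within],
                "MS": [
                    self.ss_between / self.df_between if self.df_between else np.nan,
                    self.ss_within / self.df_within if self.df_within else np.nan,
                ],
                "F": [self.f_statistic, np.nan],
                "p": [self.p_value, np.nan],
            },
            index=["between", "within"],
        )


def anova_oneway(groups: list) -> AnovaResult:
    """One-way ANOVA over a list of samples.

    With every observation identical the F ratio is undefined (0/0); this
    is reported as F = 0, p = 1 with the ``degenerate`` flag set.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    n = sum(g.size for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = k - 1, n - k
    if ssw == 0.0 and ssb == 0.0:
        return AnovaResult(0.0, 1.0, dfb, dfw, 0.0, 0.0, degenerate=True)
    if ssw == 0.0:
        return AnovaResult(np.inf, 0.0, dfb, dfw, float(ssb), 0.0)
    F = (ssb / dfb) / (ssw / dfw)
    p = float(f_dist.sf(F, dfb, dfw))
    return AnovaResult(float(F), p, dfb, dfw, float(ssb), float(ssw))


def _subject_rupture(profile, params, twist, design_kw, mesh_kw, solver_config,
                     fractions=ANATOMICAL_AREA_FRACTIONS):
    """Rupture load for one subject configuration (helper for the design)."""
    mesh = build_mesh(profile, **mesh_kw)
    mesh = label_subtendons(label_compartments(mesh), "three_way",
                            fractions=fractions)
    ff = fiber_field_from_twist(mesh, twist)
    res = run_rupture(mesh, ff, params, solver_config=solver_config,
                      **design_kw)
    return res


def run_sensitivity(subjects: list, design: SensitivityDesign | None = None,
                    mesh_kw: dict | None = None,
                    rupture_kw: dict | None = None,
                    solver_config: SolverConfig | None = None) -> pd.DataFrame:
    """One-at-a-time sensitivity of the rupture load.

    ``subjects`` is a list of dicts with keys ``id``, ``profile``,
    ``params``, ``twist``. For each subject the baseline rupture load and
    six perturbed runs (three factors x +/- sigma) are computed; the table
    has one row per run with the percent change from baseline. Failed runs
    are recorded with NaN and a warning status so the subject drops out of
    the ranking.
    """
    design = design or SensitivityDesign()
    mesh_kw = {**dict(n_axial=16, n_circ=12, n_radial=1), **(mesh_kw or {})}
    rupture_kw = rupture_kw or {}
    rows = []
    for subj in subjects:
        sid, profile = subj["id"], subj["profile"]
        params, twist = subj["params"], subj["twist"]
        base = _subject_rupture(profile, params, twist, rupture_kw, mesh_kw,
                                solver_config)
        base_load = base.rupture_load
        rows.append({"subject": sid, "factor": "baseline", "direction": 0,
                     "rupture_load": base_load,
                     "pct_change": 0.0 if base_load else np.nan,
                     "status": base.status})
        if base_load is None:
            continue
        for factor in design.factors:
            for direction in (+1, -1):
                prof_k, par_k, tw_k = profile, params, twist
                if factor == "csa":
                    scale = 1.0 + direction * design.csa_sigma_fraction
                elif factor == "c5":
                    par_k = params.replace(
                        c5=max(params.c5 + direction * design.c5_sigma, 1.0))
                else:
                    tw_k = float(np.clip(
                        twist + direction * design.twist_sigma, 0.0, 90.0))
                try:
                    if factor == "csa":
                        mesh0 = build_mesh(profile, **mesh_kw)
                        scaled = ffd_scale_csa(mesh0, scale)
                        scaled = label_subtendons(
                            label_compartments(scaled), "three_way",
                            fractions=ANATOMICAL_AREA_FRACTIONS)
                        ff = fiber_field_from_twist(scaled, tw_k)
                        res = run_rupture(scaled, ff, par_k,
                                          solver_config=solver_config,
                                          **rupture_kw)
                    else:
                        res = _subject_rupture(prof_k, par_k, tw_k,
                                               rupture_kw, mesh_kw,
                                               solver_config)
                    load = res.rupture_load
                    status = res.status
                except Exception as exc:  # constituent run failure
                    load, status = None, f"error: {exc}"
                pct = (np.nan if load is None
                       else (load - base_load) / base_load * 100.0)
                rows.append({"subject": sid, "factor": factor,
                             "direction": direction, "rupture_load": load,
                             "pct_change": pct, "status": status})
    return pd.DataFrame(rows)


def rank_factors(table: pd.DataFrame) -> pd.Series:
    """Mean absolute percent rupture-load change per factor, descending.

    Subjects with any failed run for a factor are excluded from that
    factor's mean.
    """
    t = table[table["factor"] != "baseline"]
    return (t.dropna(subset=["pct_change"])
             .groupby("factor")["pct_change"]
             .apply(lambda s: s.abs().mean())
             .sort_values(ascending=False))
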