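"""Out-of-sample prediction engines.

Everything here consumes a fitted kinetic model (point estimates or
posterior draws) and produces quantities measured in independent
experimental systems: the RTE vs mature-naive co-transfer ratio, GFP
reporter timecourses, neonatal (from-birth) trajectories with the CD8
neonatal loss modifier, derived residence-time summaries, and thymic
transplantation pool-size changes.

GFP mapping: a recent thymic emigrant is GFP+ with probability
exp(-a / T_gfp) at post-thymic age a (first-order loss of reporter
positivity), so the GFP+ probability integrates to the mean positivity
duration T_gfp over cell age.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import Lambda0Hill
from .influx import InfluxDescriptor
from .models import (
    KineticParams,
    PopulationTrajectory,
    integrated_division,
    integrated_loss,
    loss_rate,
    solve_age_structured,
)

T_BIRTH = 1.0
LIFESPAN_HORIZON = 730.0  # days; expected-sojourn integrals truncate here

__all__ = [
    "GfpMap",
    "CotransferSetup",
    "simulate_cotransfer",
    "predict_reporter_fractions",
    "estimate_gfp_duration",
    "extrapolate_to_birth",
    "mean_mn_residence_time",
    "simulate_thymus_grafts",
]


@dataclass
class GfpMap:
    """Mean duration of GFP positivity after thymic export (days)."""

    T_gfp: float

    def __post_init__(self):
        if self.T_gfp <= 0:
            raise ValueError("T_gfp must be positive")

    def p_gfp(self, a):
        return np.exp(-np.asarray(a, dtype=float) / self.T_gfp)


@dataclass
class CotransferSetup:
    """Design of the RTE/MN co-transfer experiment."""

    rte_donor_age_range: tuple = (35.0, 63.0)   # 5-9 week donors
    mn_donor_min_age: float = 98.0              # >= 14 weeks
    mn_donor_max_age: float = 140.0             # capped at 20 weeks
    initial_ratio: float = 1.0
    horizon: float = 84.0                       # days post transfer

    def __post_init__(self):
        if self.initial_ratio != 1.0:
            raise ValueError("co-transfer uses equal numbers (ratio 1)")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")


def _donor_age_distribution(p, influx, donor_age, a_step=0.5):
    traj = solve_age_structured(
        p, influx, (T_BIRTH, donor_age), t_eval=[donor_age], a_step=a_step
    )
    a = traj.ages[0]
    v = traj.u_pos[0] + traj.u_neg[0]
    return a, v


def _cohort_survival(p, a, elapsed_grid):
    """Net survival of an age-a cohort (with progeny) over elapsed time."""
    a = np.asarray(a, dtype=float)
    s = np.asarray(elapsed_grid, dtype=float)
    lam_int = (
        integrated_loss(a[:, None] + s[None, :], p) - integrated_loss(a, p)[:, None]
        - (integrated_division(a[:, None] + s[None, :], p)
           - integrated_division(a, p)[:, None])
    )
    return np.exp(-lam_int)


def simulate_cotransfer(
    p: KineticParams,
    influx: InfluxDescriptor,
    setup: Optional[CotransferSetup] = None,
    gfp: Optional[GfpMap] = None,
    draws=None,
    t_eval=None,
    hard_cutoff_age: Optional[float] = None,
) -> pd.DataFrame:
    """Predict the RTE:MN ratio timecourse after equal-number co-transfer.

    The transferred pools are built from the model cell-age distributions
    of the donor mice: the RTE pool weights cells by their GFP+ probability
    exp(-a/T_gfp), the MN pool by its complement (or by a hard cell-age
    cut-off when ``hard_cutoff_age`` is given).  Both evolve without influx
    under delta(a) and rho(a); the ratio is normalised to 1 at transfer.

    With ``draws`` (a sequence of KineticParams), returns the 2.5/50/97.5
    percentile envelope over the posterior.
    """
    setup = setup or CotransferSetup()
    gfp = gfp or GfpMap(T_gfp=11.0)
    if gfp.T_gfp < 1e-6:
        raise ValueError("degenerate GFP map: empty RTE age support")
    if t_eval is None:
        t_eval = np.linspace(0.0, setup.horizon, 25)
    t_eval = np.asarray(t_eval, dtype=float)

    def one_ratio(params):
        rte_ages = np.linspace(*setup.rte_donor_age_range, 5)
        mn_ages = np.linspace(setup.mn_donor_min_age, setup.mn_donor_max_age, 5)
        pools = {}
        for label, donor_ages, weight_fn in (
            ("rte", rte_ages, lambda a: (a <= hard_cutoff_age).astype(float)
             if hard_cutoff_age is not None else gfp.p_gfp(a)),
            ("mn", mn_ages, lambda a: (a > hard_cutoff_age).astype(float)
             if hard_cutoff_age is not None else 1.0 - gfp.p_gfp(a)),
        ):
            acc = None
            for d_age in donor_ages:
                a, v = _donor_age_distribution(params, influx, d_age)
                w = v * weight_fn(a)
                total = np.trapezoid(w, a)
                if total <= 0:
                    raise ValueError("degenerate-input: empty transferred pool")
                surv = _cohort_survival(params, a, t_eval)
                contrib = np.trapezoid(w[:, None] * surv, a, axis=0) / total
                acc = contrib if acc is None else acc + contrib
            pools[label] = acc / len(donor_ages)
        ratio = pools["rte"] / pools["mn"]
        return ratio / ratio[0]

    if draws is None:
        return pd.DataFrame({"t_days": t_eval, "ratio": one_ratio(p)})
    ratios = np.vstack([one_ratio(d) for d in draws])
    return pd.DataFrame({
        "t_days": t_eval,
        "ratio": np.median(ratios, axis=0),
        "lo2_5": np.quantile(ratios, 0.025, axis=0),
        "hi97_5": np.quantile(ratios, 0.975, axis=0),
    })


def predict_reporter_fractions(
    traj: PopulationTrajectory, gfp: GfpMap
) -> pd.DataFrame:
    """GFP+ counts and %GFP+Ki67+/- of the naive pool from an age-resolved run."""
    if traj.kind != "age":
        raise ValueError("reporter mapping requires an age-resolved trajectory")
    rows = []
    for i, t in enumerate(traj.t_grid):
        a = traj.ages[i]
        pg = gfp.p_gfp(a)
        total = np.trapezoid(traj.u_pos[i] + traj.u_neg[i], a)
        gfp_pos = np.trapezoid((traj.u_pos[i] + traj.u_neg[i]) * pg, a)
        gfp_ki_pos = np.trapezoid(traj.u_pos[i] * pg, a)
        gfp_ki_neg = np.trapezoid(traj.u_neg[i] * pg, a)
        rows.append(dict(
            t_days=float(t),
            gfp_count=float(gfp_pos),
            pct_gfp_ki67pos=float(100 * gfp_ki_pos / total) if total > 0 else np.nan,
            pct_gfp_ki67neg=float(100 * gfp_ki_neg / total) if total > 0 else np.nan,
        ))
    return pd.DataFrame(rows)


def estimate_gfp_duration(
    reporter_counts: pd.DataFrame,
    p: KineticParams,
    influx: InfluxDescriptor,
    sigma_log: float = 0.3,
    grid=None,
) -> dict:
    """One-dimensional Bayesian fit of T_gfp to GFP+ number timecourses.

    Kinetic parameters are held at their fitted values; only the mean GFP
    duration is free.  The posterior is computed by quadrature on a log
    grid (lognormal count likelihood, log-uniform prior on [1, 60] d).
    Expects columns ``t_days, gfp_count``.
    """
    t_obs = reporter_counts["t_days"].to_numpy(float)
    y = np.log(np.maximum(reporter_counts["gfp_count"].to_numpy(float), 1e-9))
    if grid is None:
        grid = np.exp(np.linspace(np.log(1.0), np.log(60.0), 320))
    traj = solve_age_structured(
        p, influx, (T_BIRTH, float(t_obs.max())), t_eval=np.unique(t_obs),
        a_step=0.5,
    )
    t_unique = np.unique(t_obs)
    logpost = np.empty(len(grid))
    pred_cache = np.empty((len(grid), len(t_unique)))
    for j, T in enumerate(grid):
        gfp = GfpMap(T_gfp=float(T))
        pred = predict_reporter_fractions(traj, gfp)["gfp_count"].to_numpy()
        pred_cache[j] = pred
        pred_obs = np.interp(t_obs, t_unique, pred)
        with np.errstate(divide="ignore"):
            lp = -0.5 * np.sum(
                ((y - np.log(np.maximum(pred_obs, 1e-300))) / sigma_log) ** 2
            )
        logpost[j] = lp
    logpost -= logpost.max()
    w = np.exp(logpost)
    w /= np.trapezoid(w, np.log(grid))
    cdf = np.concatenate([[0.0], np.cumsum(
        0.5 * (w[1:] + w[:-1]) * np.diff(np.log(grid))
    )])
    cdf /= cdf[-1]
    q = lambda u: float(np.exp(np.interp(u, cdf, np.log(grid))))
    width = q(0.975) / q(0.025)
    out = dict(median=q(0.5), lo2_5=q(0.025), hi97_5=q(0.975),
               map=float(grid[np.argmax(logpost)]),
               grid=grid, weights=w)
    if width > 10:
        out["warning"] = "flat likelihood: T_gfp weakly identified"
    return out


def extrapolate_to_birth(
    p: KineticParams,
    influx: InfluxDescriptor,
    subset: str = "CD4",
    neonatal_modifier: Optional[Lambda0Hill] = None,
    force: bool = False,
    t_eval=None,
    a_step: float = 0.25,
) -> PopulationTrajectory:
    """Run the age-structured model from a near-empty pool at 1 day of age.

    For CD8 with a neonatal modifier, cohorts exported at mouse age tau
    carry a baseline loss rate delta0 * lambda0(tau)/lambda0(inf); the
    exponential decline with cell age is unchanged.  The modifier is
    rejected for CD4 (no neonatal effect is supported there) unless
    ``force`` is set.
    """
    if neonatal_modifier is not None and subset == "CD4" and not force:
        raise ValueError(
            "neonatal modifier is a CD8-specific extension; pass force=True "
            "to apply it to CD4 anyway"
        )
    if t_eval is None:
        t_eval = np.concatenate([np.linspace(1.0, 100.0, 34),
                                 np.linspace(110.0, 300.0, 20)])
    loss_scale = neonatal_modifier.modifier_ratio if neonatal_modifier else None
    traj = solve_age_structured(
        p, influx, (T_BIRTH, float(np.max(t_eval))), t_eval=t_eval,
        a_step=a_step, loss_scale=loss_scale,
    )
    traj.loss_scale = loss_scale  # carried for residence-time summaries
    return traj


def mean_mn_residence_time(
    traj: PopulationTrajectory,
    t: float,
    a_min: float,
    p: KineticParams,
    method: str = "sojourn",
    horizon: float = LIFESPAN_HORIZON,
) -> float:
    """Mean residence time of mature naive cells (age >= a_min) at host age t.

    ``method="sojourn"`` (default) averages, over the model cell-age
    distribution, the expected further time a cell and its progeny persist
    in the pool — survival against the net loss hazard
    lambda(a) = delta(a) - rho(a), truncated at a mouse-lifespan horizon.
    ``method="instantaneous"`` averages the inverse instantaneous loss rate
    1/delta(a) instead.  Cohorts carry any neonatal baseline-loss scaling
    they were solved with.
    """
    if traj.kind != "age":
        raise ValueError("age-resolved trajectory required")
    a, upos, uneg = traj.age_distribution(t)
    if a_min >= t:
        raise ValueError("a_min must be smaller than the host age")
    u = upos + uneg
    sel = a >= a_min
    if not np.any(sel) or np.trapezoid(u[sel], a[sel]) <= 0:
        raise ValueError("empty age window")
    aa, w = a[sel], u[sel]
    loss_scale = getattr(traj, "loss_scale", None)
    scale = loss_scale(t - aa) if loss_scale is not None else np.ones_like(aa)
    if method == "instantaneous":
        vals = 1.0 / (scale * loss_rate(aa, p))
    elif method == "sojourn":
        s = np.linspace(0.0, horizon, 1500)
        haz = (
            scale[:, None] * (integrated_loss(aa[:, None] + s[None, :], p)
                              - integrated_loss(aa, p)[:, None])
            - (integrated_division(aa[:, None] + s[None, :], p)
               - integrated_division(aa, p)[:, None])
        )
        vals = np.trapezoid(np.exp(-haz), s, axis=1)
    else:
        raise ValueError("method must be 'sojourn' or 'instantaneous'")
    return float(np.trapezoid(w * vals, aa) / np.trapezoid(w, aa))


def simulate_thymus_grafts(
    p: KineticParams,
    influx: InfluxDescriptor,
    n_lobes: int,
    graft_age: float,
    t_eval=None,
) -> pd.DataFrame:
    """Pool-size fold change after transplanting extra thymic lobes.

    Two lobes make one whole extra thymus; grafting multiplies thymic
    export by (1 + n_lobes/2) from ``graft_age`` onwards.  Returns total
    counts relative to the unperturbed control, plus the excess expressed
    as days-equivalent of pre-graft thymic export.
    """
    if n_lobes < 0:
        raise ValueError("n_lobes must be >= 0")
    factor = 1.0 + n_lobes / 2.0
    if t_eval is None:
        t_eval = graft_age + np.linspace(0.0, 56.0, 15)
    t_eval = np.asarray(t_eval, dtype=float)

    phi_pos = lambda t: influx.total_influx(t) * influx.ki67_frac(t)
    phi_neg = lambda t: influx.total_influx(t) * (1 - influx.ki67_frac(t))
    boost = lambda t: np.where(np.asarray(t) >= graft_age, factor, 1.0)
    control = solve_age_structured(
        p, influx, (T_BIRTH, float(t_eval.max())), t_eval=t_eval, a_step=0.5
    )
    grafted = solve_age_structured(
        p, (lambda t: phi_pos(t) * boost(t), lambda t: phi_neg(t) * boost(t)),
        (T_BIRTH, float(t_eval.max())), t_eval=t_eval, a_step=0.5,
    )
    n_c = control.total_count()
    n_g = grafted.total_count()
    excess = n_g - n_c
    export_rate = influx.total_influx(t_eval) * (factor - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        days_equiv = np.where(export_rate > 0, excess / export_rate, 0.0)
    return pd.DataFrame({
        "t_days": t_eval,
        "fold_change": n_g / n_c,
        "excess_cells": excess,
        "excess_days_of_export": days_equiv,
    })
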