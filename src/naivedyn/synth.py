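"""Seeded generators for the four dataset schemas.

Each generator draws noisy observations around the forward model with the
statistical structure the analyses assume — lognormal multiplicative noise
on counts, logit-normal noise on fractions, staggered sampling ages — and
is a pure function of (parameters, design, seed).

Default designs mirror the study conditions: three bone-marrow-transplant
age groups of ~35 mice each with observation ages running from four weeks
post-BMT out to 600 days; reporter mice aged 10–120 days; fate-mapping
cohorts labelled at three host ages and bled at six timepoints.  Default
noise (count CV 0.2, logit SD 0.25) approximates the scatter of the
published timecourses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import cohort_curve
from .inference import model_observables
from .influx import InfluxDescriptor
from .models import KineticParams, solve_age_structured
from .predictions import GfpMap, predict_reporter_fractions

T_BIRTH = 1.0

__all__ = [
    "NoiseSpec",
    "ChimeraDesign",
    "CohortDesign",
    "generate_sp_timecourse",
    "generate_chimera_dataset",
    "generate_cohort_dataset",
    "generate_reporter_dataset",
]


@dataclass
class NoiseSpec:
    count_cv: float = 0.2    # lognormal coefficient of variation on counts
    frac_sd: float = 0.25    # SD on the logit scale for fractions
    seed: int = 0

    def __post_init__(self):
        if self.count_cv < 0 or self.frac_sd < 0:
            raise ValueError("noise scales must be >= 0")

    @property
    def sigma_log(self):
        """Lognormal sigma equivalent to the requested CV."""
        return float(np.sqrt(np.log1p(self.count_cv ** 2)))

    def rng(self):
        return np.random.default_rng(self.seed)


def _noisy_counts(rng, values, noise: NoiseSpec):
    if noise.count_cv == 0:
        return np.asarray(values, dtype=float)
    return values * np.exp(noise.sigma_log * rng.standard_normal(len(values)))


def _noisy_fractions(rng, values, noise: NoiseSpec, eps=1e-4):
    values = np.clip(np.asarray(values, dtype=float), eps, 1 - eps)
    if noise.frac_sd == 0:
        return values
    z = np.log(values / (1 - values)) + noise.frac_sd * rng.standard_normal(
        len(values)
    )
    return np.clip(1 / (1 + np.exp(-z)), eps, 1 - eps)


# ---------------------------------------------------------------------------
# SP thymocyte timecourses
# ---------------------------------------------------------------------------

def generate_sp_timecourse(
    true_descriptor: InfluxDescriptor,
    ages=None,
    noise: NoiseSpec = None,
) -> pd.DataFrame:
    """Noisy SP thymocyte counts and Ki67+ fractions vs mouse age."""
    noise = noise or NoiseSpec()
    rng = noise.rng()
    if ages is None:
        ages = np.concatenate([
            np.linspace(4, 20, 8), np.linspace(25, 100, 12),
            np.linspace(120, 300, 10),
        ])
    ages = np.asarray(ages, dtype=float)
    counts = _noisy_counts(rng, true_descriptor.sp_count(ages), noise)
    k = _noisy_fractions(rng, true_descriptor.ki67_frac(ages), noise)
    return pd.DataFrame({
        "mouse_age_days": ages,
        "subset": true_descriptor.subset,
        "sp_count": counts,
        "sp_ki67_frac": k,
    })


# ---------------------------------------------------------------------------
# busulfan chimera datasets
# ---------------------------------------------------------------------------

@dataclass
class ChimeraDesign:
    n_per_group: int = 35
    bmt_age_groups: tuple = ((49.0, 63.0), (77.0, 105.0), (140.0, 175.0))
    min_follow_up: float = 28.0   # donor cells detectable ~4 weeks post BMT
    max_age: float = 600.0
    subset: str = "CD4"
    chimerism: float = 0.85       # stable DP1 donor chimerism


def generate_chimera_dataset(
    p: KineticParams,
    influx: InfluxDescriptor,
    design: ChimeraDesign = None,
    noise: NoiseSpec = None,
) -> pd.DataFrame:
    """Cross-sectional chimera observations from the forward model.

    Each mouse has one BMT age (uniform within its group), one observation
    age (uniform between BMT + follow-up and the design maximum) and four
    noisy observable streams.
    """
    design = design or ChimeraDesign()
    noise = noise or NoiseSpec()
    rng = noise.rng()
    t_bmt, t_obs, groups = [], [], []
    for gi, (lo, hi) in enumerate(design.bmt_age_groups):
        b = rng.uniform(lo, hi, size=design.n_per_group)
        o = rng.uniform(b + design.min_follow_up, design.max_age)
        t_bmt.append(b)
        t_obs.append(o)
        groups.append(np.full(design.n_per_group, gi))
    t_bmt = np.concatenate(t_bmt)
    t_obs = np.concatenate(t_obs)
    groups = np.concatenate(groups)
    streams = model_observables(
        p, influx, t_obs, t_bmt, chimerism=design.chimerism, t0=T_BIRTH
    )
    df = pd.DataFrame({
        "mouse_id": [f"m{i:03d}" for i in range(len(t_obs))],
        "group": groups,
        "host_age": t_obs,
        "age_at_bmt": t_bmt,
        "subset": design.subset,
        "total_count": _noisy_counts(rng, streams["total"], noise),
        "fd": _noisy_fractions(rng, streams["fd"], noise),
        "ki67_host": _noisy_fractions(rng, streams["ki67_host"], noise),
        "ki67_donor": _noisy_fractions(rng, streams["ki67_donor"], noise),
    })
    return df


# ---------------------------------------------------------------------------
# fate-mapping cohort datasets
# ---------------------------------------------------------------------------

@dataclass
class CohortDesign:
    group_ages: tuple = (21.0, 42.0, 84.0)   # host age at tamoxifen
    n_mice_per_group: int = 5
    sample_times: tuple = (7.0, 14.0, 28.0, 42.0, 63.0, 90.0)
    n0_median: float = 2e5
    n0_sdlog: float = 0.3


def generate_cohort_dataset(
    lambda0_by_group,
    r_lambda: float,
    design: CohortDesign = None,
    noise: NoiseSpec = None,
) -> pd.DataFrame:
    """Time-stamped labelled-cohort timecourses with mouse-level N0."""
    design = design or CohortDesign()
    noise = noise or NoiseSpec()
    rng = noise.rng()
    lambda0_by_group = np.asarray(lambda0_by_group, dtype=float)
    if len(lambda0_by_group) != len(design.group_ages):
        raise ValueError("one lambda0 per group age required")
    rows = []
    times = np.asarray(design.sample_times, dtype=float)
    for gi, (g_age, lam) in enumerate(zip(design.group_ages, lambda0_by_group)):
        for mi in range(design.n_mice_per_group):
            n0 = design.n0_median * np.exp(
                design.n0_sdlog * rng.standard_normal()
            )
            clean = cohort_curve(n0, lam, r_lambda, times)
            counts = _noisy_counts(rng, clean, noise)
            for t, c in zip(times, counts):
                rows.append(dict(
                    mouse_id=f"g{gi}_m{mi}", group_age_days=g_age,
                    time_since_label_days=float(t), labelled_count=float(c),
                ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dual-reporter datasets
# ---------------------------------------------------------------------------

def generate_reporter_dataset(
    p: KineticParams,
    influx: InfluxDescriptor,
    gfp: GfpMap,
    ages=None,
    noise: NoiseSpec = None,
    loss_scale=None,
) -> pd.DataFrame:
    """GFP+ counts and %GFP+Ki67+/- in reporter mice aged 10-120 days."""
    noise = noise or NoiseSpec()
    rng = noise.rng()
    if ages is None:
        ages = np.linspace(10.0, 120.0, 23)
    ages = np.asarray(ages, dtype=float)
    traj = solve_age_structured(
        p, influx, (T_BIRTH, float(ages.max())), t_eval=ages, a_step=0.25,
        loss_scale=loss_scale,
    )
    clean = predict_reporter_fractions(traj, gfp)
    pos = np.clip(clean["pct_gfp_ki67pos"].to_numpy() / 100.0, 0, 1)
    neg = np.clip(clean["pct_gfp_ki67neg"].to_numpy() / 100.0, 0, 1)
    return pd.DataFrame({
        "t_days": ages,
        "gfp_count": _noisy_counts(rng, clean["gfp_count"].to_numpy(), noise),
        "pct_gfp_ki67pos": 100 * _noisy_fractions(rng, pos, noise),
        "pct_gfp_ki67neg": 100 * _noisy_fractions(rng, neg, noise),
    })
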