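"""Forward solvers for the candidate models of naive T cell dynamics.

Six variants are supported, all with binary Ki67 structure and thymic
influx, and with host/donor bookkeeping for the busulfan chimera system:

* ``neutral``      — constant per-cell loss rate delta0 and division rate rho0;
* ``dd_loss``      — loss modulated by pool size, delta0 * (N/N_ref)^gamma;
* ``dd_division``  — division modulated by pool size (LIP-style feedback);
* ``rte_mn``       — recent thymic emigrants and mature naive cells with
  distinct rates, linked by a constant maturation rate mu;
* ``age_loss``     — loss rate declines exponentially with post-thymic cell
  age, delta(a) = delta0 * exp(-r_delta * a);
* ``age_division`` — division rate grows exponentially with cell age,
  rho(a) = rho0 * exp(+r_rho * a).

The age-structured variants are solved along characteristics (cell age and
mouse age advance together).  Because the dynamics are linear and
lineage-blind, two closed-form reductions make the solution cheap and
stable:

1. the total density along a characteristic propagates as
   ``v(a) = v(0) * exp(Irho(a) - Idelta(a))`` with both integrated rates
   available in closed form;
2. the Ki67+ fraction ``W = u+/(u+ + u-)`` obeys
   ``dW/da = 2 rho(a) - (2 rho(a) + beta) W`` — independent of the loss
   rate — which is integrated exactly in log space.

Division bookkeeping: a dividing Ki67- mother yields two Ki67+ daughters
(-1 to Ki67-, +2 to Ki67+); a dividing Ki67+ mother adds net +1 to Ki67+.
Ki67 reverts to negative at the constant rate beta (default 1/3.5 per day,
the ~3.5-day detectability window of the protein).

Donor labelling: after bone marrow transplant at ``t_bmt`` the thymic
export stream carries the stable bone-marrow chimerism ``chi`` of donor
cells; a cohort entering at time tau >= t_bmt (+ optional transit delay) is
donor with probability chi.  The normalised donor fraction fd therefore
equals the fraction of cells that entered after t_bmt, and is bounded by 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .influx import InfluxDescriptor

DAYS_PER_MONTH = 30.44
KI67_BETA = 1.0 / 3.5  # day^-1; Ki67 detectable ~3-4 days after division

VARIANTS = ("neutral", "dd_loss", "dd_division", "rte_mn", "age_loss", "age_division")

__all__ = [
    "KineticParams",
    "PopulationTrajectory",
    "loss_rate",
    "division_rate",
    "solve_age_structured",
    "solve_compartmental",
    "observables_from_trajectory",
    "DAYS_PER_MONTH",
    "KI67_BETA",
    "VARIANTS",
]


@dataclass
class KineticParams:
    """Per-subset rate constants for one model variant (all rates in day^-1)."""

    variant: str = "age_loss"
    delta0: float = 1.0 / 22.0     # loss rate of cells of age 0
    r_delta: float = np.log(2) / 92.0   # decline rate of loss with cell age
    rho0: float = 1.0 / (18 * DAYS_PER_MONTH)  # division rate of cells of age 0
    r_rho: float = 0.0             # growth rate of division with cell age
    beta: float = KI67_BETA        # Ki67+ -> Ki67- transition rate
    mu: float = 0.0                # RTE -> MN maturation rate (rte_mn only)
    psi: float = 0.07              # export per SP thymocyte per day
    gamma: float = 0.0             # density-dependence exponent
    n_ref: float = 1e7             # pool-size scale for density dependence
    delta_mn: Optional[float] = None  # MN loss rate (rte_mn only)
    rho_mn: Optional[float] = None    # MN division rate (rte_mn only)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")
        for name in ("delta0", "r_delta", "rho0", "r_rho", "beta", "mu", "psi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # --- derived quantities ----------------------------------------------
    def residence_time(self, a=0.0):
        """1/delta(a): expected residence time of a cell of age a (days)."""
        return 1.0 / loss_rate(a, self)

    def interdivision_time(self, a=0.0, units="days"):
        rho = division_rate(a, self)
        t = np.inf if np.all(rho == 0) else 1.0 / rho
        return t / DAYS_PER_MONTH if units == "months" else t


def loss_rate(a, p: KineticParams):
    """delta(a): instantaneous per-cell loss rate at post-thymic age a."""
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("cell age must be >= 0")
    if p.variant == "age_loss":
        return p.delta0 * np.exp(-p.r_delta * a)
    return np.broadcast_to(np.float64(p.delta0), a.shape).copy() if a.shape else p.delta0


def division_rate(a, p: KineticParams):
    """rho(a): instantaneous per-cell division rate at post-thymic age a."""
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("cell age must be >= 0")
    if p.variant == "age_division":
        return p.rho0 * np.exp(p.r_rho * a)
    return np.broadcast_to(np.float64(p.rho0), a.shape).copy() if a.shape else p.rho0


# ---------------------------------------------------------------------------
# closed-form characteristic machinery (age-structured and neutral variants)
# ---------------------------------------------------------------------------

def _expm1_ratio(x):
    """(e^x - 1)/x, series-safe at x=0."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    out[nz] = np.expm1(x[nz]) / x[nz]
    return out


def integrated_loss(a, p: KineticParams):
    """Integral of delta over cell age [0, a] (unit modifier scale)."""
    a = np.asarray(a, dtype=float)
    if p.variant == "age_loss" and p.r_delta > 0:
        return p.delta0 * (1.0 - np.exp(-p.r_delta * a)) / p.r_delta
    return p.delta0 * a


def integrated_division(a, p: KineticParams):
    """Integral of rho over cell age [0, a]."""
    a = np.asarray(a, dtype=float)
    if p.variant == "age_division" and p.r_rho > 0:
        return p.rho0 * a * _expm1_ratio(p.r_rho * a)
    return p.rho0 * a


@dataclass
class CharacteristicTables:
    """Precomputed closed-form solution pieces on a master cell-age grid.

    ``g = exp(Irho - Idelta)`` is the total-density propagator (for unit
    loss-rate scale; a baseline-loss modifier ``m`` enters as
    ``exp(Irho - m*Idelta)``).  ``C = 2*Irho + beta*a`` drives the Ki67
    fraction, which along any characteristic is
    ``W(a) = alpha(a) + exp(-C(a)) * W(0)``.
    """

    a: np.ndarray
    i_delta: np.ndarray
    i_rho: np.ndarray
    C: np.ndarray
    alpha: np.ndarray

    def w_decay(self, a):
        return np.exp(-np.interp(a, self.a, self.C))

    def interp(self, a):
        a = np.asarray(a, dtype=float)
        return (
            np.interp(a, self.a, self.i_delta),
            np.interp(a, self.a, self.i_rho),
            np.interp(a, self.a, self.C),
            np.interp(a, self.a, self.alpha),
        )


def characteristic_tables(p: KineticParams, a_max: float = None,
                          a_step: float = 0.25, grid=None):
    """Build the closed-form tables up to cell age ``a_max`` (or on ``grid``)."""
    if grid is not None:
        a = np.asarray(grid, dtype=float)
    else:
        n = max(int(np.ceil(a_max / a_step)) + 1, 4)
        a = np.linspace(0.0, max(a_max, a_step), n)
    i_delta = integrated_loss(a, p)
    i_rho = integrated_division(a, p)
    C = 2.0 * i_rho + p.beta * a
    rho = division_rate(a, p)
    # alpha(a) = int_0^a 2 rho(s) exp(-(C(a)-C(s))) ds, via log-space cumsum
    with np.errstate(divide="ignore"):
        l = np.log(2.0 * rho) + C
    h = np.diff(a)
    seg = np.logaddexp(l[:-1], l[1:]) + np.log(h / 2.0)
    log_t = np.concatenate([[-np.inf], np.logaddexp.accumulate(seg)])
    alpha = np.exp(log_t - C)
    return CharacteristicTables(a=a, i_delta=i_delta, i_rho=i_rho, C=C, alpha=alpha)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class PopulationTrajectory:
    """Model state over mouse age, with host/donor bookkeeping.

    For age-structured solutions, ``ages[i]`` is the cell-age grid at mouse
    age ``t_grid[i]`` and ``u_pos[i]/u_neg[i]`` are Ki67+/- densities
    (cells per day of age, all lineages pooled; the donor share of a cohort
    is ``chimerism`` for entry times >= t_bmt + delay, zero before).
    Compartmental solutions store counts per (epoch, ki67) compartment.
    """

    kind: str                      # "age" or "compartment"
    variant: str
    t_grid: np.ndarray
    t_bmt: Optional[float] = None
    chimerism: float = 1.0
    bmt_delay: float = 0.0
    # age-structured payload
    ages: list = field(default_factory=list)
    u_pos: list = field(default_factory=list)
    u_neg: list = field(default_factory=list)
    # compartmental payload: dict name -> array over t_grid
    counts: dict = field(default_factory=dict)
    params: Optional[KineticParams] = None

    def _post_mask(self, i):
        t = self.t_grid[i]
        a = self.ages[i]
        if self.t_bmt is None:
            return np.zeros_like(a, dtype=bool)
        return (t - a) >= (self.t_bmt + self.bmt_delay)

    def _integrate(self, i, which="both", entry="all"):
        a = self.ages[i]
        u = {
            "pos": self.u_pos[i],
            "neg": self.u_neg[i],
            "both": self.u_pos[i] + self.u_neg[i],
        }[which]
        if entry == "all":
            w = np.ones_like(a)
        else:
            post = self._post_mask(i)
            w = post.astype(float) if entry == "post" else (~post).astype(float)
        return float(np.trapezoid(u * w, a))

    def total_count(self):
        if self.kind == "age":
            return np.array([self._integrate(i) for i in range(len(self.t_grid))])
        return sum(v for v in self.counts.values())

    def ki67_pos_count(self):
        if self.kind == "age":
            return np.array(
                [self._integrate(i, "pos") for i in range(len(self.t_grid))]
            )
        return sum(v for k, v in self.counts.items() if k.endswith("+"))

    def ki67_fraction(self):
        tot = self.total_count()
        return np.divide(
            self.ki67_pos_count(), tot, out=np.full_like(tot, np.nan), where=tot > 0
        )

    def age_distribution(self, t):
        """(ages, u_pos, u_neg) at the stored time closest to ``t``."""
        if self.kind != "age":
            raise ValueError("age distribution requires an age-resolved trajectory")
        i = int(np.argmin(np.abs(self.t_grid - t)))
        return self.ages[i], self.u_pos[i], self.u_neg[i]

    def to_tidy_frame(self, age_bin=7.0):
        """Tidy long-format export of densities (age-structured only)."""
        rows = []
        for i, t in enumerate(self.t_grid):
            a = self.ages[i]
            post = self._post_mask(i)
            edges = np.arange(0.0, a.max() + age_bin, age_bin)
            for lo, hi in zip(edges[:-1], edges[1:]):
                sel = (a >= lo) & (a < hi)
                if not sel.any():
                    continue
                for state, u in (("+", self.u_pos[i]), ("-", self.u_neg[i])):
                    for lineage, w in (
                        ("donor", post.astype(float) * self.chimerism),
                        ("host", 1.0 - post.astype(float) * self.chimerism),
                    ):
                        dens = float(np.trapezoid(u[sel] * w[sel], a[sel]))
                        rows.append(
                            dict(
                                t_days=float(t), lineage=lineage, ki67_state=state,
                                age_bin_lo=float(lo), age_bin_hi=float(hi),
                                density=dens,
                            )
                        )
        return pd.DataFrame(rows)


def _as_influx_functions(influx):
    """Accept an InfluxDescriptor or a (phi_pos(t), phi_neg(t)) pair."""
    if isinstance(influx, InfluxDescriptor):
        return (
            lambda t: influx.total_influx(t) * influx.ki67_frac(t),
            lambda t: influx.total_influx(t) * (1.0 - influx.ki67_frac(t)),
        )
    phi_pos, phi_neg = influx
    return phi_pos, phi_neg


def solve_age_structured(
    p: KineticParams,
    influx,
    t_span,
    t_bmt: Optional[float] = None,
    a_step: float = 0.25,
    t_eval=None,
    chimerism: float = 1.0,
    bmt_delay: float = 0.0,
    initial_pool=None,
    loss_scale: Optional[Callable] = None,
) -> PopulationTrajectory:
    """Solve the age-structured transport system along characteristics.

    Parameters
    ----------
    influx : InfluxDescriptor or pair of callables (phi_pos, phi_neg)
        Boundary condition u^{+/-}(a=0, t).
    t_span : (t0, t1) in days of mouse age.
    t_eval : mouse ages at which to store the solution (default: 8 points).
    initial_pool : optional (ages0, u_pos0, u_neg0) densities at t0.
    loss_scale : optional callable m(tau) scaling the baseline loss rate
        delta0 per thymic-entry time tau (the neonatal modifier).
    """
    if p.variant not in ("age_loss", "age_division", "neutral"):
        raise ValueError(
            "solve_age_structured supports age-structured (and neutral) "
            f"variants, not {p.variant!r}"
        )
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t1 <= t0:
        raise ValueError("t_span must be increasing")
    phi_pos, phi_neg = _as_influx_functions(influx)
    if t_eval is None:
        t_eval = np.linspace(t0, t1, 8)
    t_eval = np.atleast_1d(np.asarray(t_eval, dtype=float))

    extra = 0.0
    if initial_pool is not None:
        extra = float(np.max(initial_pool[0]))
    tables = characteristic_tables(p, a_max=(t1 - t0) + extra + a_step, a_step=a_step)

    traj = PopulationTrajectory(
        kind="age", variant=p.variant, t_grid=t_eval, t_bmt=t_bmt,
        chimerism=chimerism, bmt_delay=bmt_delay, params=p,
    )
    for t in t_eval:
        # influx-born characteristics: entry tau in [t0, t], age a = t - tau
        n = max(int(np.ceil((t - t0) / a_step)), 1) + 1
        a = np.linspace(0.0, t - t0, n)
        tau = t - a
        i_d, i_r, C, alpha = tables.interp(a)
        scale = loss_scale(tau) if loss_scale is not None else 1.0
        phi_p, phi_n = phi_pos(tau), phi_neg(tau)
        v0 = phi_p + phi_n
        with np.errstate(divide="ignore", invalid="ignore"):
            w0 = np.where(v0 > 0, phi_p / np.maximum(v0, 1e-300), 0.0)
        v = v0 * np.exp(i_r - scale * i_d)
        w = alpha + np.exp(-C) * w0
        if initial_pool is not None:
            a0, up0, un0 = (np.asarray(x, dtype=float) for x in initial_pool)
            a_now = a0 + (t - t0)
            i_d0, i_r0, C0, alpha0 = tables.interp(a0)
            i_dn, i_rn, Cn, alphan = tables.interp(a_now)
            tau0 = t0 - a0
            sc0 = loss_scale(tau0) if loss_scale is not None else 1.0
            v_init0 = up0 + un0
            v_init = v_init0 * np.exp((i_rn - i_r0) - sc0 * (i_dn - i_d0))
            with np.errstate(divide="ignore", invalid="ignore"):
                w_init0 = np.where(v_init0 > 0, up0 / np.maximum(v_init0, 1e-300), 0.0)
            decay = np.exp(-(Cn - C0))
            w_init = (alphan - alpha0 * decay) + decay * w_init0
            a = np.concatenate([a, a_now])
            v = np.concatenate([v, v_init])
            w = np.concatenate([w, w_init])
            order = np.argsort(a, kind="stable")
            a, v, w = a[order], v[order], w[order]
        if np.any(v < -1e-9 * max(v.max(initial=0.0), 1.0)):
            raise RuntimeError("solver fault: negative densities")
        traj.ages.append(a)
        traj.u_pos.append(v * np.clip(w, 0.0, 1.0))
        traj.u_neg.append(v * np.clip(1.0 - w, 0.0, 1.0))
    return traj


def solve_compartmental(
    p: KineticParams,
    influx,
    t_span,
    t_bmt: Optional[float] = None,
    t_eval=None,
    chimerism: float = 1.0,
    initial_counts=None,
    rtol: float = 1e-8,
    atol: float = 1e-6,
) -> PopulationTrajectory:
    """Integrate the compartmental ODE systems (neutral, dd_*, rte_mn).

    States are split by entry epoch (pre/post BMT) and Ki67; the rte_mn
    variant additionally carries RTE and MN compartments.  Density-dependent
    variants modulate delta or rho by (N_total/N_ref)^gamma.
    """
    if p.variant not in ("neutral", "dd_loss", "dd_division", "rte_mn"):
        raise ValueError(f"solve_compartmental does not handle {p.variant!r}")
    t0, t1 = float(t_span[0]), float(t_span[1])
    phi_pos, phi_neg = _as_influx_functions(influx)
    if t_eval is None:
        t_eval = np.linspace(t0, t1, 60)
    t_eval = np.atleast_1d(np.asarray(t_eval, dtype=float))
    is_rte = p.variant == "rte_mn"
    n_per_epoch = 4 if is_rte else 2

    d_mn = p.delta_mn if p.delta_mn is not None else p.delta0
    r_mn = p.rho_mn if p.rho_mn is not None else p.rho0

    def epoch_deriv(y, fp, fn, delta_r, rho_r, delta_m, rho_m):
        if is_rte:
            Rp, Rn, Mp, Mn = y
            dRp = fp + 2 * rho_r * Rn + rho_r * Rp - (p.beta + delta_r + p.mu) * Rp
            dRn = fn + p.beta * Rp - (rho_r + delta_r + p.mu) * Rn
            dMp = p.mu * Rp + 2 * rho_m * Mn + rho_m * Mp - (p.beta + delta_m) * Mp
            dMn = p.mu * Rn + p.beta * Mp - (rho_m + delta_m) * Mn
            return [dRp, dRn, dMp, dMn]
        Np, Nn = y
        dNp = fp + 2 * rho_r * Nn + rho_r * Np - (p.beta + delta_r) * Np
        dNn = fn + p.beta * Np - (rho_r + delta_r) * Nn
        return [dNp, dNn]

    def rhs(t, y):
        N = float(np.sum(y))
        mod = (max(N, 1.0) / p.n_ref) ** p.gamma if p.gamma != 0 else 1.0
        delta = p.delta0 * mod if p.variant == "dd_loss" else p.delta0
        rho = p.rho0 * mod if p.variant == "dd_division" else p.rho0
        dm = d_mn * mod if p.variant == "dd_loss" else d_mn
        rm = r_mn * mod if p.variant == "dd_division" else r_mn
        fp, fn = float(phi_pos(t)), float(phi_neg(t))
        post = t_bmt is not None and t >= t_bmt
        pre = y[:n_per_epoch]
        pos = y[n_per_epoch:]
        d_pre = epoch_deriv(pre, 0.0 if post else fp, 0.0 if post else fn,
                            delta, rho, dm, rm)
        d_post = epoch_deriv(pos, fp if post else 0.0, fn if post else 0.0,
                             delta, rho, dm, rm)
        return np.concatenate([d_pre, d_post])

    y0 = np.zeros(2 * n_per_epoch)
    if initial_counts is not None:
        y0[: len(initial_counts)] = initial_counts
    sol = solve_ivp(
        rhs, (t0, t1), y0, t_eval=t_eval, method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"stiff integration failure: {sol.message}")
    y = np.clip(sol.y, 0.0, None)
    names = (
        ["pre_rte+", "pre_rte-", "pre_mn+", "pre_mn-",
         "post_rte+", "post_rte-", "post_mn+", "post_mn-"]
        if is_rte
        else ["pre+", "pre-", "post+", "post-"]
    )
    counts = {name: y[i] for i, name in enumerate(names)}
    return PopulationTrajectory(
        kind="compartment", variant=p.variant, t_grid=sol.t, t_bmt=t_bmt,
        chimerism=chimerism, counts=counts, params=p,
    )


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

@dataclass
class Observables:
    t_days: np.ndarray
    total_count: np.ndarray
    fd: np.ndarray
    ki67_host: np.ndarray
    ki67_donor: np.ndarray

    def to_frame(self):
        return pd.DataFrame(
            dict(
                t_days=self.t_days, total_count=self.total_count, fd=self.fd,
                ki67_host=self.ki67_host, ki67_donor=self.ki67_donor,
            )
        )


def observables_from_trajectory(
    traj: PopulationTrajectory, reference_chimerism: float = 1.0
) -> Observables:
    """Map a model trajectory to the four fitted observable streams.

    fd is the donor fraction normalised to the bone-marrow (DP1) chimerism:
    with post-BMT export carrying a donor share equal to the reference
    chimerism, fd reduces to the fraction of cells that entered the pool
    after BMT, and saturates at 1 under complete turnover.  The Ki67+
    fraction within host cells mixes pre-BMT survivors with the host share
    of post-BMT entrants; donor Ki67 is undefined (NaN) while the donor
    pool is empty.
    """
    if not (0.0 < reference_chimerism <= 1.0):
        raise ValueError("reference_chimerism must be in (0, 1]")
    chi = reference_chimerism
    nt = len(traj.t_grid)
    tot = np.zeros(nt)
    fd = np.zeros(nt)
    k_host = np.full(nt, np.nan)
    k_donor = np.full(nt, np.nan)
    if traj.kind == "age":
        for i in range(nt):
            n_all = traj._integrate(i, "both", "all")
            n_post = traj._integrate(i, "both", "post")
            kp_all = traj._integrate(i, "pos", "all")
            kp_post = traj._integrate(i, "pos", "post")
            n_pre, kp_pre = n_all - n_post, kp_all - kp_post
            tot[i] = n_all
            fd[i] = n_post / n_all if n_all > 0 else 0.0
            host_n = n_pre + (1 - chi) * n_post
            if host_n > 0:
                k_host[i] = (kp_pre + (1 - chi) * kp_post) / host_n
            if n_post > 0:
                k_donor[i] = kp_post / n_post
    else:
        c = traj.counts
        pos_keys = [k for k in c if k.endswith("+")]
        post_keys = [k for k in c if k.startswith("post")]
        n_all = sum(c[k] for k in c)
        n_post = sum(c[k] for k in post_keys)
        kp_all = sum(c[k] for k in pos_keys)
        kp_post = sum(c[k] for k in pos_keys if k.startswith("post"))
        tot = n_all
        with np.errstate(divide="ignore", invalid="ignore"):
            fd = np.where(n_all > 0, n_post / np.maximum(n_all, 1e-300), 0.0)
            host_n = (n_all - n_post) + (1 - chi) * n_post
            k_host = np.where(
                host_n > 0,
                ((kp_all - kp_post) + (1 - chi) * kp_post) / np.maximum(host_n, 1e-300),
                np.nan,
            )
            k_donor = np.where(
                n_post > 0, kp_post / np.maximum(n_post, 1e-300), np.nan
            )
    fd = np.clip(fd, 0.0, 1.0)
    return Observables(
        t_days=np.asarray(traj.t_grid, dtype=float), total_count=tot, fd=fd,
        ki67_host=k_host, ki67_donor=k_donor,
    )
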