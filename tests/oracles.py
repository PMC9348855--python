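"""Independent oracles used to validate the production solvers.

These deliberately share no code with the package's characteristic
solver: a first-order upwind finite-difference scheme for the
age-structured transport system, an individual-based stochastic
simulation, and an exact leave-one-out refit for a conjugate
normal-mean model.
"""

import numpy as np

from naivedyn.models import KineticParams, division_rate, loss_rate


def upwind_fd_solver(p: KineticParams, phi_pos, phi_neg, t0, t1, da=0.25,
                     cfl=0.5, t_checkpoints=()):
    """First-order upwind finite differences on the (a, t) grid.

    Returns dict t -> (a_grid, u_pos, u_neg).  Advection at unit speed in
    cell age with influx as the age-0 boundary density.
    """
    a = np.arange(0.0, (t1 - t0) + da, da)
    dt = cfl * da
    delta = loss_rate(a, p)
    rho = division_rate(a, p)
    up = np.zeros_like(a)
    un = np.zeros_like(a)
    out = {}
    checkpoints = sorted(t_checkpoints)
    ci = 0
    t = t0
    n_steps = int(np.ceil((t1 - t0) / dt))
    for _ in range(n_steps):
        up[0] = phi_pos(t)
        un[0] = phi_neg(t)
        dup = np.zeros_like(up)
        dun = np.zeros_like(un)
        dup[1:] = -(up[1:] - up[:-1]) / da
        dun[1:] = -(un[1:] - un[:-1]) / da
        dup += 2 * rho * un + rho * up - (p.beta + delta) * up
        dun += p.beta * up - (rho + delta) * un
        dup[0] = dun[0] = 0.0  # boundary cells are re-imposed each step
        up = np.clip(up + dt * dup, 0.0, None)
        un = np.clip(un + dt * dun, 0.0, None)
        t += dt
        while ci < len(checkpoints) and t >= checkpoints[ci] - 1e-9:
            up[0] = phi_pos(t)
            un[0] = phi_neg(t)
            out[checkpoints[ci]] = (a.copy(), up.copy(), un.copy())
            ci += 1
    return out


def stochastic_simulation(p: KineticParams, phi_pos, phi_neg, t0, t1, dt=0.05,
                          rng=None, t_checkpoints=()):
    """Individual-based simulation with per-cell ages and Ki67 states.

    Influx is Poisson; death, division and Ki67 reversion are Bernoulli
    events per step.  A division marks the mother Ki67+ and adds one
    Ki67+ daughter with the mother's post-thymic age.
    Returns dict t -> (total, ki67_pos_total).
    """
    rng = rng or np.random.default_rng(0)
    ages = np.empty(0)
    pos = np.empty(0, dtype=bool)
    out = {}
    checkpoints = sorted(t_checkpoints)
    ci = 0
    t = t0
    n_steps = int(np.ceil((t1 - t0) / dt))
    for _ in range(n_steps):
        lam_p = phi_pos(t) * dt
        lam_n = phi_neg(t) * dt
        n_new_p = rng.poisson(lam_p)
        n_new_n = rng.poisson(lam_n)
        new_ages = rng.uniform(0.0, dt, n_new_p + n_new_n)
        new_pos = np.concatenate([np.ones(n_new_p, bool), np.zeros(n_new_n, bool)])
        delta = loss_rate(ages, p) if len(ages) else np.empty(0)
        rho = division_rate(ages, p) if len(ages) else np.empty(0)
        u = rng.random(len(ages))
        die = u < delta * dt
        divide = (~die) & (u < (delta + rho) * dt)
        revert = pos & (rng.random(len(ages)) < p.beta * dt)
        pos = pos & ~revert
        daughters = ages[divide]
        pos[divide] = True
        keep = ~die
        ages = np.concatenate([ages[keep] + dt, daughters + dt, new_ages])
        pos = np.concatenate([pos[keep], np.ones(len(daughters), bool), new_pos])
        t += dt
        while ci < len(checkpoints) and t >= checkpoints[ci] - 1e-9:
            out[checkpoints[ci]] = (len(ages), int(pos.sum()))
            ci += 1
    return out


def exact_loo_normal_mean(y, sigma, mu0, tau0):
    """Exact LOO elpd for y_i ~ N(mu, sigma^2), mu ~ N(mu0, tau0^2).

    The posterior predictive after leaving out observation i is normal
    with moments available in closed form.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    elpd_i = np.empty(n)
    for i in range(n):
        rest = np.delete(y, i)
        prec = 1 / tau0 ** 2 + len(rest) / sigma ** 2
        mu_n = (mu0 / tau0 ** 2 + rest.sum() / sigma ** 2) / prec
        var_pred = 1 / prec + sigma ** 2
        elpd_i[i] = (-0.5 * np.log(2 * np.pi * var_pred)
                     - 0.5 * (y[i] - mu_n) ** 2 / var_pred)
    return elpd_i
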