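"""Kinetic model solvers: rates, closed forms, reductions, invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import naivedyn as nd
from naivedyn.models import (
    DAYS_PER_MONTH,
    KineticParams,
    observables_from_trajectory,
    solve_age_structured,
    solve_compartmental,
)

LN2 = np.log(2)


class TestRates:
    def test_age0_residence_time_is_22_days(self):
        p = KineticParams(variant="age_loss", delta0=1 / 22, r_delta=LN2 / 92)
        assert nd.loss_rate(0.0, p) == pytest.approx(0.04545, rel=1e-3)
        assert p.residence_time(0.0) == pytest.approx(22.0)

    def test_loss_halves_at_halving_age(self):
        p = KineticParams(variant="age_loss", delta0=1 / 22, r_delta=LN2 / 92)
        assert nd.loss_rate(92.0, p) == pytest.approx(nd.loss_rate(0.0, p) / 2)

    def test_r_delta_zero_gives_constant_loss(self):
        p = KineticParams(variant="age_loss", delta0=0.05, r_delta=0.0)
        a = np.linspace(0, 300, 7)
        assert np.allclose(nd.loss_rate(a, p), 0.05)

    def test_interdivision_time_18_months(self):
        p = KineticParams(variant="age_division", rho0=1 / (18 * DAYS_PER_MONTH),
                          r_rho=LN2 / (10 * DAYS_PER_MONTH))
        assert p.interdivision_time(0.0, units="months") == pytest.approx(18.0)
        assert nd.division_rate(10 * DAYS_PER_MONTH, p) == pytest.approx(
            2 * nd.division_rate(0.0, p))

    def test_zero_division(self):
        p = KineticParams(variant="neutral", rho0=0.0)
        assert np.all(nd.division_rate(np.linspace(0, 500, 9), p) == 0)

    def test_negative_age_rejected(self):
        p = KineticParams()
        with pytest.raises(ValueError):
            nd.loss_rate(-1.0, p)
        with pytest.raises(ValueError):
            nd.division_rate(-0.5, p)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(variant="telepathic")


class TestClosedForms:
    def test_closed_pool_exponential_decay(self, zero_influx):
        p = KineticParams(variant="neutral", delta0=0.05, rho0=0.0, beta=0.0)
        ages0 = np.linspace(0, 10, 101)
        u0 = np.full_like(ages0, 50.0)
        traj = solve_age_structured(
            p, zero_influx, (1.0, 41.0), t_eval=[1.0, 21.0, 41.0],
            initial_pool=(ages0, u0, u0),
        )
        n = traj.total_count()
        assert np.allclose(n / n[0], np.exp(-0.05 * np.array([0, 20, 40])),
                           rtol=1e-6)

    def test_constant_influx_linear_growth_without_turnover(self):
        p = KineticParams(variant="neutral", delta0=0.0, rho0=0.0)
        phi = (lambda t: np.full_like(np.asarray(t, float), 30.0),
               lambda t: np.full_like(np.asarray(t, float), 70.0))
        traj = solve_age_structured(p, phi, (1.0, 101.0),
                                    t_eval=[1.0, 51.0, 101.0], a_step=0.1)
        n = traj.total_count()
        assert n == pytest.approx(100.0 * np.array([0.0, 50.0, 100.0]), rel=1e-6)

    def test_ki67_cohort_decay_exp_beta(self, zero_influx):
        """A closed all-Ki67+ cohort loses positivity as exp(-beta t)."""
        p = KineticParams(variant="neutral", delta0=0.02, rho0=0.0)
        ages0 = np.linspace(0, 5, 51)
        u0 = np.full_like(ages0, 10.0)
        traj = solve_age_structured(
            p, zero_influx, (1.0, 15.0), t_eval=[1.0, 8.0, 15.0],
            initial_pool=(ages0, u0, np.zeros_like(u0)),
        )
        f = traj.ki67_fraction()
        assert np.allclose(f, np.exp(-np.array([0.0, 7.0, 14.0]) / 3.5),
                           rtol=1e-6)


class TestReductions:
    def test_dd_gamma_zero_equals_neutral(self, cd4_influx):
        base = dict(delta0=1 / 30, rho0=1 / 400)
        t_eval = np.linspace(1, 300, 12)
        t_dd = solve_compartmental(KineticParams(variant="dd_loss", gamma=0.0,
                                                 **base),
                                   cd4_influx, (1.0, 300.0), t_bmt=100.0,
                                   t_eval=t_eval)
        t_ne = solve_compartmental(KineticParams(variant="neutral", **base),
                                   cd4_influx, (1.0, 300.0), t_bmt=100.0,
                                   t_eval=t_eval)
        assert np.allclose(t_dd.total_count(), t_ne.total_count(), rtol=1e-6)
        assert np.allclose(t_dd.ki67_fraction(), t_ne.ki67_fraction(), rtol=1e-6)

    def test_rte_mn_fast_maturation_approaches_neutral(self, cd4_influx):
        """With mu -> infinity the RTE/MN model collapses onto the MN kinetics."""
        mn = dict(delta0=1 / 40, rho0=1 / 500)
        p_rte = KineticParams(variant="rte_mn", delta0=1 / 15, rho0=1 / 200,
                              mu=1e3, delta_mn=mn["delta0"], rho_mn=mn["rho0"])
        p_neu = KineticParams(variant="neutral", **mn)
        t_eval = np.linspace(1, 250, 10)
        tr = solve_compartmental(p_rte, cd4_influx, (1.0, 250.0), t_eval=t_eval)
        tn = solve_compartmental(p_neu, cd4_influx, (1.0, 250.0), t_eval=t_eval)
        assert np.allclose(tr.total_count()[1:], tn.total_count()[1:], rtol=2e-3)

    def test_age_structured_r_zero_matches_compartmental_neutral(self, cd4_influx):
        p = KineticParams(variant="neutral", delta0=1 / 25, rho0=1 / 450)
        t_eval = np.linspace(1, 400, 9)
        ta = solve_age_structured(p, cd4_influx, (1.0, 400.0), t_eval=t_eval,
                                  a_step=0.1)
        tc = solve_compartmental(p, cd4_influx, (1.0, 400.0), t_eval=t_eval)
        assert np.allclose(ta.total_count()[1:], tc.total_count()[1:], rtol=2e-3)
        assert np.allclose(ta.ki67_fraction()[1:], tc.ki67_fraction()[1:],
                           rtol=5e-3)


class TestInvariantsAndObservables:
    def test_mass_balance(self, cd4_params, cd4_influx):
        """d(total)/dt equals influx plus net growth at every stored step."""
        t_eval = np.linspace(50.0, 54.0, 41)
        traj = solve_age_structured(cd4_params, cd4_influx, (1.0, 54.0),
                                    t_eval=t_eval, a_step=0.05)
        n = traj.total_count()
        dndt = np.gradient(n, t_eval)
        for i in (10, 20, 30):
            a, up, un = traj.ages[i], traj.u_pos[i], traj.u_neg[i]
            u = up + un
            rho_bar = np.trapezoid(nd.division_rate(a, cd4_params) * u, a)
            delta_bar = np.trapezoid(nd.loss_rate(a, cd4_params) * u, a)
            expected = cd4_influx.total_influx(t_eval[i]) + rho_bar - delta_bar
            assert dndt[i] == pytest.approx(expected, rel=2e-2)

    def test_positivity(self, cd4_params, cd4_influx):
        traj = solve_age_structured(cd4_params, cd4_influx, (1.0, 300.0),
                                    t_eval=np.linspace(1, 300, 7))
        for up, un in zip(traj.u_pos, traj.u_neg):
            assert np.all(up >= 0) and np.all(un >= 0)

    def test_ki67_shadow_is_young(self, cd4_influx):
        """Without division, peripheral Ki67+ cells are recent emigrants:
        almost none are older than two weeks, and their median age is a
        few days."""
        p = KineticParams(variant="age_loss", delta0=1 / 22,
                          r_delta=LN2 / 92, rho0=0.0)
        traj = solve_age_structured(p, cd4_influx, (1.0, 300.0),
                                    t_eval=[300.0], a_step=0.1)
        a, up, _ = traj.age_distribution(300.0)
        old = np.trapezoid(np.where(a > 14, up, 0.0), a)
        tot = np.trapezoid(up, a)
        assert old / tot < 0.015
        cum = np.cumsum(up) / up.sum()
        assert a[np.searchsorted(cum, 0.5)] < 5.0

    def test_fd_saturates_below_one(self, cd4_params, cd4_influx):
        t_eval = np.array([100.0, 200.0, 400.0, 600.0])
        traj = solve_age_structured(cd4_params, cd4_influx, (1.0, 600.0),
                                    t_eval=t_eval, t_bmt=70.0, chimerism=0.85)
        obs = observables_from_trajectory(traj, reference_chimerism=0.85)
        assert np.all(np.diff(obs.fd[:3]) > 0)          # rises after BMT
        assert np.all(obs.fd < 1.0)                     # incomplete replacement
        assert obs.fd[-1] > 0.5

    def test_host_donor_ki67_converge(self, cd4_params, cd4_influx):
        """Host and donor Ki67 fractions differ soon after BMT and converge
        within 6-12 months."""
        t_eval = np.array([100.0, 250.0, 430.0])   # BMT at 70 d
        traj = solve_age_structured(cd4_params, cd4_influx, (1.0, 430.0),
                                    t_eval=t_eval, t_bmt=70.0, chimerism=0.85)
        obs = observables_from_trajectory(traj, reference_chimerism=0.85)
        gap = np.abs(obs.ki67_donor - obs.ki67_host)
        assert obs.ki67_donor[0] > obs.ki67_host[0]
        assert gap[-1] < 0.25 * gap[0]

    def test_all_donor_pool_gives_fd_one(self, cd4_params, cd4_influx):
        traj = solve_age_structured(cd4_params, cd4_influx, (1.0, 200.0),
                                    t_eval=[200.0], t_bmt=0.5, chimerism=1.0)
        obs = observables_from_trajectory(traj, reference_chimerism=1.0)
        assert obs.fd[0] == pytest.approx(1.0, abs=1e-9)
        assert np.isnan(obs.ki67_host[0])  # no host cells remain

    def test_empty_donor_pool_flagged_missing(self, cd4_params, cd4_influx):
        traj = solve_age_structured(cd4_params, cd4_influx, (1.0, 50.0),
                                    t_eval=[50.0], t_bmt=400.0)
        obs = observables_from_trajectory(traj, reference_chimerism=0.85)
        assert np.isnan(obs.ki67_donor[0])
        assert obs.fd[0] == 0.0

    def test_reference_chimerism_domain(self, cd4_params, cd4_influx):
        traj = solve_age_structured(cd4_params, cd4_influx, (1.0, 50.0),
                                    t_eval=[50.0])
        with pytest.raises(ValueError):
            observables_from_trajectory(traj, reference_chimerism=1.5)

    @given(delta0=st.floats(1e-3, 0.2), rho0=st.floats(0.0, 0.01))
    def test_total_counts_nonnegative_for_any_rates(self, delta0, rho0,
                                                    cd4_influx):
        p = KineticParams(variant="age_loss", delta0=delta0,
                          r_delta=0.005, rho0=rho0)
        traj = solve_age_structured(p, cd4_influx, (1.0, 120.0),
                                    t_eval=[60.0, 120.0], a_step=1.0)
        assert np.all(traj.total_count() >= 0)


class TestExports:
    def test_tidy_frame_and_observables_csv(self, cd4_params, cd4_influx,
                                            tmp_path):
        traj = solve_age_structured(cd4_params, cd4_influx, (1.0, 120.0),
                                    t_eval=[60.0, 120.0], t_bmt=56.0,
                                    chimerism=0.85)
        tidy = traj.to_tidy_frame()
        assert set(tidy.columns) == {"t_days", "lineage", "ki67_state",
                                     "age_bin_lo", "age_bin_hi", "density"}
        # binned densities integrate back to the totals
        tot = tidy.groupby("t_days")["density"].sum().to_numpy()
        assert np.allclose(tot, traj.total_count(), rtol=5e-2)
        obs = observables_from_trajectory(traj, 0.85).to_frame()
        p = tmp_path / "obs.csv"
        obs.to_csv(p, index=False)
        assert list(obs.columns) == ["t_days", "total_count", "fd",
                                     "ki67_host", "ki67_donor"]
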