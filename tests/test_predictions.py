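"""Out-of-sample prediction engines."""

import numpy as np
import pytest

import naivedyn as nd
from naivedyn.models import KineticParams
from naivedyn.predictions import (
    CotransferSetup,
    GfpMap,
    estimate_gfp_duration,
    extrapolate_to_birth,
    mean_mn_residence_time,
    predict_reporter_fractions,
    simulate_cotransfer,
    simulate_thymus_grafts,
)
from naivedyn.synth import NoiseSpec, generate_reporter_dataset


class TestGfpMap:
    def test_probability_one_at_export_and_mean_duration_identity(self):
        gfp = GfpMap(T_gfp=11.0)
        assert gfp.p_gfp(0.0) == 1.0
        a = np.linspace(0, 600, 60001)
        assert np.trapezoid(gfp.p_gfp(a), a) == pytest.approx(11.0, rel=1e-4)

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            GfpMap(T_gfp=0.0)


class TestCotransfer:
    def test_age_independent_kinetics_keep_ratio_at_one(self, cd4_influx):
        p = KineticParams(variant="neutral", delta0=1 / 30, rho0=1 / 500)
        df = simulate_cotransfer(p, cd4_influx)
        assert np.allclose(df["ratio"], 1.0, atol=1e-9)

    def test_age_loss_ratio_declines_monotonically(self, cd4_params,
                                                   cd4_influx):
        df = simulate_cotransfer(cd4_params, cd4_influx)
        assert np.all(np.diff(df["ratio"]) < 0)
        assert df["ratio"].iloc[-1] < 0.85

    def test_weak_age_division_effect_keeps_ratio_near_one(self, cd4_influx):
        p = nd.reference_params("CD4", "age_division")
        df = simulate_cotransfer(p, cd4_influx,
                                 CotransferSetup(horizon=42.0))
        assert np.all(df["ratio"] > 0.95)

    def test_ratio_invariant_to_transferred_numbers(self, cd4_params,
                                                    cd4_influx):
        """Linearity: scaling thymic output leaves the ratio unchanged."""
        from dataclasses import replace
        big = replace(cd4_influx, psi=cd4_influx.psi * 7.0)
        r1 = simulate_cotransfer(cd4_params, cd4_influx)["ratio"]
        r2 = simulate_cotransfer(cd4_params, big)["ratio"]
        assert np.allclose(r1, r2, rtol=1e-9)

    def test_posterior_draw_envelope(self, cd4_params, cd4_influx):
        from dataclasses import replace
        draws = [replace(cd4_params, delta0=d)
                 for d in (1 / 18, 1 / 22, 1 / 28)]
        df = simulate_cotransfer(cd4_params, cd4_influx, draws=draws,
                                 t_eval=np.linspace(0, 42, 8))
        assert {"lo2_5", "ratio", "hi97_5"} <= set(df.columns)
        assert np.all(df["lo2_5"] <= df["ratio"] + 1e-12)
        assert np.all(df["ratio"] <= df["hi97_5"] + 1e-12)

    def test_degenerate_gfp_map_rejected(self, cd4_params, cd4_influx):
        with pytest.raises(ValueError):
            simulate_cotransfer(cd4_params, cd4_influx,
                                gfp=GfpMap(T_gfp=1e-9))


class TestReporter:
    def test_infinite_gfp_duration_recovers_total_counts(self, cd4_params,
                                                         cd4_influx):
        traj = extrapolate_to_birth(cd4_params, cd4_influx,
                                    t_eval=[30.0, 90.0])
        df = predict_reporter_fractions(traj, GfpMap(T_gfp=1e9))
        assert np.allclose(df["gfp_count"], traj.total_count(), rtol=1e-6)

    def test_no_division_and_ki67neg_influx_gives_zero_gfp_ki67pos(self):
        from naivedyn.influx import InfluxDescriptor
        desc = InfluxDescriptor(ki67_params=(0.0, 1e-3, 5.0))  # kappa ~ 0
        assert np.allclose(desc.ki67_frac(np.linspace(1, 300, 10)), 0.0)
        p = KineticParams(variant="age_loss", delta0=1 / 22,
                          r_delta=np.log(2) / 92, rho0=0.0)
        traj = nd.solve_age_structured(p, desc, (1.0, 90.0), t_eval=[90.0])
        df = predict_reporter_fractions(traj, GfpMap(T_gfp=10.0))
        assert df["pct_gfp_ki67pos"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_compartmental_trajectory_unsupported(self, cd4_influx):
        p = KineticParams(variant="neutral", delta0=1 / 30, rho0=0.0)
        traj = nd.solve_compartmental(p, cd4_influx, (1.0, 60.0))
        with pytest.raises(ValueError, match="age-resolved"):
            predict_reporter_fractions(traj, GfpMap(T_gfp=10.0))

    def test_neonatal_gfp_fraction_shapes(self, cd4_params, cd4_influx):
        """%GFP+Ki67+ falls steeply over ages 10-120 d; %GFP+Ki67- falls
        more slowly."""
        traj = extrapolate_to_birth(cd4_params, cd4_influx,
                                    t_eval=np.linspace(10, 120, 12))
        df = predict_reporter_fractions(traj, GfpMap(T_gfp=11.0))
        pos, neg = df["pct_gfp_ki67pos"], df["pct_gfp_ki67neg"]
        assert pos.iloc[0] / pos.iloc[-1] > 5
        assert neg.iloc[0] / neg.iloc[-1] < pos.iloc[0] / pos.iloc[-1]
        assert np.all(np.diff(pos) < 0)


class TestGfpDuration:
    def test_noise_free_recovery_to_three_figures(self, cd4_params,
                                                  cd4_influx):
        data = generate_reporter_dataset(cd4_params, cd4_influx,
                                         GfpMap(T_gfp=11.0),
                                         noise=NoiseSpec(0.0, 0.0, seed=0))
        est = estimate_gfp_duration(data, cd4_params, cd4_influx,
                                    sigma_log=0.05)
        assert est["map"] == pytest.approx(11.0, rel=5e-3)  # 3 significant figures

    def test_noisy_recovery_covers_truth(self, cd4_params, cd4_influx):
        data = generate_reporter_dataset(cd4_params, cd4_influx,
                                         GfpMap(T_gfp=11.0),
                                         noise=NoiseSpec(0.2, 0.2, seed=8))
        est = estimate_gfp_duration(data, cd4_params, cd4_influx,
                                    sigma_log=0.2)
        assert est["lo2_5"] < 11.0 < est["hi97_5"]
        assert "warning" not in est


class TestBirthExtrapolation:
    def test_zero_influx_from_birth_gives_empty_pool(self, cd4_params):
        from naivedyn.influx import InfluxDescriptor
        desc = InfluxDescriptor(psi=0.0)
        traj = extrapolate_to_birth(cd4_params, desc, t_eval=[30.0, 90.0])
        assert np.allclose(traj.total_count(), 0.0)

    def test_cd4_modifier_rejected_without_force(self, cd4_params, cd4_influx,
                                                 neonatal_modifier):
        with pytest.raises(ValueError, match="CD8-specific"):
            extrapolate_to_birth(cd4_params, cd4_influx, subset="CD4",
                                 neonatal_modifier=neonatal_modifier)
        extrapolate_to_birth(cd4_params, cd4_influx, subset="CD4",
                             neonatal_modifier=neonatal_modifier, force=True,
                             t_eval=[30.0])

    def test_neonatal_ki67_high_then_low(self, cd4_params, cd4_influx):
        """Ki67+ fraction exceeds 60% in the first week of life and falls
        to a few percent by three months."""
        traj = extrapolate_to_birth(cd4_params, cd4_influx,
                                    t_eval=[5.0, 90.0])
        f = traj.ki67_fraction()
        assert f[0] > 0.60
        assert 0.01 < f[1] < 0.05

    def test_modifier_improves_neonatal_cd8_match(self, cd8_params,
                                                  cd8_influx,
                                                  neonatal_modifier):
        """Data generated with elevated neonatal loss are predicted better
        by the modified model than by the adult-only model."""
        gfp = GfpMap(T_gfp=8.0)
        data = generate_reporter_dataset(
            cd8_params, cd8_influx, gfp, noise=NoiseSpec(0.0, 0.0, seed=0),
            loss_scale=neonatal_modifier.modifier_ratio)
        ages = data["t_days"].to_numpy()
        res = {}
        for label, mod in (("with", neonatal_modifier), ("without", None)):
            traj = extrapolate_to_birth(cd8_params, cd8_influx, "CD8",
                                        neonatal_modifier=mod, t_eval=ages)
            pred = predict_reporter_fractions(traj, gfp)
            res[label] = np.sum(
                (pred["pct_gfp_ki67neg"].to_numpy()
                 - data["pct_gfp_ki67neg"].to_numpy()) ** 2)
        assert res["with"] < 0.2 * res["without"]

    def test_modifier_effect_fades_with_host_age(self, cd8_params, cd8_influx,
                                                 neonatal_modifier):
        te = [110.0, 300.0, 450.0]
        t0 = extrapolate_to_birth(cd8_params, cd8_influx, "CD8", t_eval=te)
        t1 = extrapolate_to_birth(cd8_params, cd8_influx, "CD8",
                                  neonatal_modifier=neonatal_modifier,
                                  t_eval=te)
        rel = np.abs(t1.total_count() / t0.total_count() - 1)
        assert np.all(np.diff(rel) < 0)          # shrinks with age
        kf = np.abs(t1.ki67_fraction() / t0.ki67_fraction() - 1)
        assert np.all(kf[1:] < 0.02)             # Ki67 kinetics ~unchanged


class TestResidenceTime:
    def test_constant_loss_returns_inverse_rate(self, cd4_influx):
        p = KineticParams(variant="neutral", delta0=0.05, rho0=0.0)
        traj = nd.solve_age_structured(p, cd4_influx, (1.0, 84.0),
                                       t_eval=[84.0])
        for method in ("instantaneous", "sojourn"):
            val = mean_mn_residence_time(traj, 84.0, 21.0, p, method=method)
            assert val == pytest.approx(20.0, rel=1e-3)

    def test_increases_with_host_age_under_age_loss(self, cd4_params,
                                                    cd4_influx):
        vals = []
        for t in (84.0, 180.0, 365.0):
            traj = extrapolate_to_birth(cd4_params, cd4_influx, t_eval=[t])
            vals.append(mean_mn_residence_time(traj, t, 21.0, cd4_params))
        assert vals[0] < vals[1] < vals[2]

    def test_empty_age_window_rejected(self, cd4_params, cd4_influx):
        traj = extrapolate_to_birth(cd4_params, cd4_influx, t_eval=[30.0])
        with pytest.raises(ValueError):
            mean_mn_residence_time(traj, 30.0, 40.0, cd4_params)


class TestThymusGrafts:
    def test_no_lobes_no_change(self, cd4_params, cd4_influx):
        df = simulate_thymus_grafts(cd4_params, cd4_influx, 0, 56.0)
        assert np.allclose(df["fold_change"], 1.0, rtol=1e-9)

    def test_steady_state_fold_change_approaches_lobe_factor(self):
        """With age-independent loss and stationary influx the fold change
        tends to (1 + n_lobes/2) as thymic output dominates the pool."""
        from naivedyn.influx import InfluxDescriptor
        desc = InfluxDescriptor(count_params=(np.log(1e6), 0.0, 5.0), psi=0.05)
        p = KineticParams(variant="neutral", delta0=0.2, rho0=0.0)
        df = simulate_thymus_grafts(p, desc, 6, 100.0,
                                    t_eval=[100.0, 200.0, 300.0])
        assert df["fold_change"].iloc[-1] == pytest.approx(4.0, rel=2e-2)

    def test_excess_equals_weeks_of_export_cd4(self, cd4_params, cd4_influx):
        """Excess cells after grafting 6 lobes correspond to roughly the
        preceding ~3 weeks of extra thymic export."""
        df = simulate_thymus_grafts(cd4_params, cd4_influx, 6, 56.0)
        final = df["excess_days_of_export"].iloc[-1]
        assert 14.0 <= final <= 35.0

    def test_negative_lobes_rejected(self, cd4_params, cd4_influx):
        with pytest.raises(ValueError):
            simulate_thymus_grafts(cd4_params, cd4_influx, -2, 56.0)
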