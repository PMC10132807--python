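"""Trial orchestration: initialization, spread metric, epochs, sweeps."""

import numpy as np
import pytest
from dataclasses import replace

import ompsim as om


class TestInitialization:
    def test_tau0_is_nominal_over_segments(self, small_config):
        cfg = replace(
            small_config,
            chain=om.ChainConfig(n_segments=10, n_axons=4),
            experiment=replace(small_config.experiment, p_tau=0.0),
        )
        chain, _ = om.initialize_run(cfg, seed=0)
        for seg in chain.segments:
            np.testing.assert_allclose(seg.tau, 50.0 / 10)

    def test_initial_spread_scales_with_p_tau(self, small_config):
        cfg = replace(
            small_config,
            chain=om.ChainConfig(n_segments=2, n_axons=100),
            experiment=replace(small_config.experiment, p_tau=5.0),
        )
        draws = []
        for s in range(50):
            chain, _ = om.initialize_run(cfg, seed=s)
            draws.append(np.concatenate([seg.tau for seg in chain.segments]))
        sd = np.std(np.concatenate(draws))
        assert sd == pytest.approx(0.05 * 25.0, rel=0.05)

    def test_M_zero_and_lambda_R_balance(self, small_config):
        chain, _ = om.initialize_run(small_config, seed=1)
        for seg in chain.segments:
            assert np.all(seg.M == 0)
            assert seg.lambda_R == pytest.approx(
                om.balance_removal_rate(0.02, 4, 100.0)
            )

    def test_fixed_delay_spread_exact(self, small_config):
        _, fixed = om.initialize_run(small_config, seed=2)
        assert np.std(fixed.D) == pytest.approx(5.0, abs=1e-12)

    def test_spread_adds_in_quadrature(self, small_config):
        # sigma_tau(0)^2 = sigma_D^2 + Var(sum of per-segment draws)
        cfg = replace(
            small_config, chain=om.ChainConfig(n_segments=2, n_axons=200)
        )
        chain, fixed = om.initialize_run(cfg, seed=3)
        tau_tot = chain.total_tau()
        s0 = om.spread_metric(fixed, tau_tot)
        expect = np.sqrt(np.var(fixed.D) + np.var(tau_tot))
        # cross-covariance of independent draws vanishes only on average
        assert s0 == pytest.approx(expect, rel=0.05)


class TestSpreadMetric:
    def test_perfect_synchrony(self):
        f = om.FixedDelays(D=np.array([-10.0, 10.0]), sigma_D=10.0)
        assert om.spread_metric(f, np.array([25.0, 5.0])) == 0.0

    def test_population_sd(self):
        f = om.FixedDelays(D=np.array([-10.0, 10.0]), sigma_D=10.0)
        assert om.spread_metric(f, np.zeros(2)) == pytest.approx(10.0)

    def test_single_axon_rejected(self):
        f = om.FixedDelays(D=np.array([1.0]), sigma_D=0.0)
        with pytest.raises(ValueError):
            om.spread_metric(f, np.array([0.0]))


class TestRunTrial:
    def test_frozen_system_keeps_initial_spread(self, small_config):
        # lambda_M = 0 and lambda_R0 = 0: no plasticity at all
        cfg = replace(
            small_config,
            plasticity=om.OMPParams(lambda_M=0.0, lambda_H=0.0, lambda_R0=0.0),
        )
        prof = om.run_trial(cfg, seed=4)
        np.testing.assert_allclose(prof.sigma_tau, prof.sigma_tau0, rtol=1e-12)

    def test_profile_shape_and_times(self, small_config):
        prof = om.run_trial(small_config, seed=5)
        assert prof.n_epochs == 5
        np.testing.assert_allclose(prof.times, 4e3 * np.arange(1, 6))
        assert np.all(np.isfinite(prof.sigma_tau))
        assert prof.sigma_tau0 > 0

    def test_trial_deterministic(self, small_config):
        p1 = om.run_trial(small_config, seed=6)
        p2 = om.run_trial(small_config, seed=6)
        np.testing.assert_array_equal(p1.sigma_tau, p2.sigma_tau)

    def test_warmup_freezes_delays(self, small_config):
        cfg = replace(
            small_config,
            plasticity=replace(small_config.plasticity, lambda_H=1e-5),
            experiment=replace(small_config.experiment, warmup_epochs=2),
        )
        prof = om.run_trial(cfg, seed=7)
        assert prof.meta["warmup_epochs"] == 2
        # learning clock starts after warm-up: times still n_e epochs long
        assert prof.n_epochs == cfg.experiment.n_e

    def test_fixed_delay_override(self, small_config):
        D = np.array([-3.0, -1.0, 1.0, 3.0])
        prof = om.run_trial(small_config, seed=8, fixed_delays=D)
        assert prof.sigma_D_only == pytest.approx(np.std(D))

    def test_traces_recorded(self, small_config):
        prof = om.run_trial(small_config, seed=9, record_traces=True)
        n_e, n_o, n_a = 5, 2, 4
        assert prof.traces["mean_M"].shape == (n_e, n_o, n_a)
        assert prof.traces["mean_tau"].shape == (n_e, n_o, n_a)
        assert prof.traces["lambda_R"].shape == (n_e, n_o)
        assert np.all(prof.traces["mean_M"] >= 0)
        # epoch-mean delays stay near tau_0 for a short run
        assert np.all(np.abs(prof.traces["mean_tau"] - 25.0) < 5.0)


class TestSweep:
    def test_bookkeeping_and_determinism(self, small_config):
        grid = {"kernel.tau_G": [5.0, 10.0], "signal.sigma_j": [0.0, 1.0]}
        profs = om.sweep(small_config, grid, n_r=2, seed=42)
        assert len(profs) == 8
        seeds = [p.meta["sweep_index"] for p in profs]
        assert len(set(seeds)) == 8
        profs2 = om.sweep(small_config, grid, n_r=2, seed=42)
        for a, b in zip(profs, profs2):
            np.testing.assert_array_equal(a.sigma_tau, b.sigma_tau)

    def test_group_means_match_direct_average(self, small_config):
        grid = {"kernel.tau_G": [5.0, 10.0]}
        profs = om.sweep(small_config, grid, n_r=2, seed=1)
        frame = om.profiles_to_frame(profs)
        by_hand = np.mean(
            [p.sigma_tau for p in profs if p.meta["params"]["kernel.tau_G"] == 5.0],
            axis=0,
        )
        grp = (
            frame[frame["kernel.tau_G"] == 5.0]
            .groupby("epoch")["sigma_tau_ms"]
            .mean()
            .to_numpy()
        )
        np.testing.assert_allclose(grp, by_hand)

    def test_event_guard_triggers(self, small_config):
        big = replace(
            small_config,
            experiment=replace(small_config.experiment, T_exp=1e9),
        )
        with pytest.raises(RuntimeError, match="max_events"):
            om.sweep(big, {"kernel.tau_G": [10.0]}, n_r=1, seed=0)

    def test_profile_export(self, small_config, tmp_path):
        profs = om.sweep(small_config, {"kernel.tau_G": [10.0]}, n_r=1, seed=3)
        out = tmp_path / "profiles.tsv"
        man = tmp_path / "manifest.tsv"
        om.export_profiles(profs, out, man)
        assert out.exists() and man.exists()
        import pandas as pd

        frame = pd.read_csv(out, sep="\t")
        assert {"run_id", "epoch", "time_ms", "sigma_tau_ms"} <= set(frame.columns)


class TestConfigRoundtrip:
    def test_yaml_roundtrip(self, small_config, tmp_path):
        path = tmp_path / "run.yaml"
        small_config.save(path)
        back = om.RunConfig.load(path)
        assert back.kernel.tau_r == small_config.kernel.tau_r
        assert back.plasticity.lambda_M == small_config.plasticity.lambda_M
        assert back.chain.n_segments == small_config.chain.n_segments
        assert back.signal[0].tau_s == small_config.signal[0].tau_s
        prof_a = om.run_trial(small_config, seed=11)
        prof_b = om.run_trial(back, seed=11)
        np.testing.assert_array_equal(prof_a.sigma_tau, prof_b.sigma_tau)
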