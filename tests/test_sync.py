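import numpy as np
import pytest

import repsync
from repsync import (CostConfig, CouplingSpec, ObservationSet,
                     add_observation_noise, extended_distance, nqe,
                     noise_floor, primary_rhs, secondary_rhs,
                     simulate_observations, sync_distance)
from repsync.model import N_STATE, default_initial_state
from repsync.sync import EXTENDED_CHANNELS, SyncCost, _distance


class TestSecondaryRHS:
    def test_equals_primary_when_uncoupled(self, theta_star, rng):
        y = rng.uniform(0, 20, N_STATE)
        spec = CouplingSpec(D=0.0)
        np.testing.assert_allclose(secondary_rhs(y, theta_star, [1.0, 2.0], spec),
                                   primary_rhs(y, theta_star), rtol=1e-12)

    def test_zero_coupling_term_when_matching(self, theta_star, rng):
        y = rng.uniform(0, 20, N_STATE)
        spec = CouplingSpec(D=7.0)
        u = y[[0, 7]]
        np.testing.assert_allclose(secondary_rhs(y, theta_star, u, spec),
                                   primary_rhs(y, theta_star), rtol=1e-12)

    def test_coupling_appears_only_on_coupled_equations(self, theta_star, rng):
        y = rng.uniform(0, 20, N_STATE)
        spec = CouplingSpec(D=4.0)
        u = np.array([3.0, 9.0])
        diff = secondary_rhs(y, theta_star, u, spec) - primary_rhs(y, theta_star)
        expected = np.zeros(N_STATE)
        expected[0] = spec.D * (u[0] - y[0])
        expected[7] = spec.D * (u[1] - y[7])
        np.testing.assert_allclose(diff, expected, rtol=1e-12, atol=1e-12)

    def test_channel_count_mismatch_rejected(self, theta_star):
        with pytest.raises(ValueError, match="observed channels"):
            secondary_rhs(np.ones(N_STATE), theta_star, [1.0],
                          CouplingSpec())

    def test_coupling_spec_validation(self):
        assert CouplingSpec().validate() == []
        assert CouplingSpec(observed_channels=(0,)).validate()
        assert CouplingSpec(observed_channels=(0, 1)).validate()
        with pytest.raises(ValueError):
            CouplingSpec(D=-1.0)


class TestSimulateObservations:
    def test_deterministic_given_seed(self, theta_star):
        a = simulate_observations(theta_star, seed=5)
        b = simulate_observations(theta_star, seed=5)
        np.testing.assert_array_equal(a.channels, b.channels)

    def test_default_channels_first_variable_of_each_cell(self, obs_clean):
        assert obs_clean.channel_indices == (0, 7)

    def test_sampling_at_dt_matches_trajectory_columns(self, theta_star):
        from repsync.integrate import integrate_network
        x0 = default_initial_state()
        cfg = CostConfig(T=2.0, transient=0.0, sample_step=0.01)
        obs = simulate_observations(theta_star, x0=x0, cfg=cfg,
                                    primary_transient=0.0)
        _, samples, _ = integrate_network(theta_star, x0, 0.01, 2.0,
                                          channels=[0, 7])
        np.testing.assert_allclose(obs.channels, samples, rtol=1e-12)

    def test_extended_mode_records_eight_channels(self, theta_star):
        cfg = CostConfig(T=5.0, transient=0.0, extended=True)
        obs = simulate_observations(theta_star, seed=0, cfg=cfg)
        assert obs.channel_indices == EXTENDED_CHANNELS

    def test_csv_round_trip_with_sidecar(self, tmp_path, obs_clean):
        noisy = add_observation_noise(obs_clean, 0.05, seed=3)
        path = tmp_path / "obs.csv"
        noisy.to_csv(path)
        again = ObservationSet.from_csv(path)
        np.testing.assert_allclose(again.channels, noisy.channels, rtol=1e-8)
        assert again.noise_sigma == pytest.approx(0.05)
        assert again.channel_indices == noisy.channel_indices


class TestSyncDistance:
    def test_self_driven_secondary_gives_near_zero(self, theta_star):
        # observations generated from the very trajectory the secondary
        # follows, same y0: the coupling term vanishes along the solution
        y0 = default_initial_state()
        cfg = CostConfig(T=10.0, transient=0.0, sample_step=0.01)
        obs = simulate_observations(theta_star, x0=y0, cfg=cfg,
                                    primary_transient=0.0)
        d = sync_distance(theta_star, obs, CouplingSpec(D=3.0), cfg, y0)
        # zero up to the O(dt^2) approximation of the drive at stage times
        assert d < 1e-5

    def test_truth_beats_inflated_parameters(self, theta_star, obs_clean,
                                             y0_alt):
        cfg = CostConfig()
        d_true = sync_distance(theta_star, obs_clean, cfg=cfg, y0=y0_alt)
        d_bad = sync_distance(theta_star.replace(n=theta_star.n * 1.1),
                              obs_clean, cfg=cfg, y0=y0_alt)
        assert d_true < d_bad

    def test_direct_summation_oracle(self, theta_star, obs_clean, y0_alt):
        from repsync import _core
        cfg = CostConfig(T=5.0, transient=1.0)
        spec = CouplingSpec()
        d = sync_distance(theta_star, obs_clean, spec, cfg, y0_alt)
        # recompute by hand on the sampled grid
        dt = 0.01
        n_steps = int(round(cfg.total_time / dt))
        grid = np.arange(n_steps + 1) * dt
        u = np.column_stack([np.interp(grid, obs_clean.times,
                                       obs_clean.column(c))
                             for c in spec.observed_channels])
        stride = int(round(cfg.sample_step / dt))
        first = int(round(cfg.transient / dt))
        sample_idx = np.arange(first, n_steps + 1, stride, dtype=np.int64)
        samples, _, _ = _core.rk2_drive(
            np.asarray(y0_alt, float), theta_star.to_array(), dt, n_steps, u,
            np.array(spec.observed_channels, dtype=np.int64), spec.D,
            sample_idx, np.array(spec.observed_channels, dtype=np.int64),
            False)
        total = 0.0
        for k in range(len(sample_idx)):
            for j, c in enumerate(spec.observed_channels):
                uo = np.interp(sample_idx[k] * dt, obs_clean.times,
                               obs_clean.column(c))
                total += (uo - samples[k, j]) ** 2
        assert d == pytest.approx(total / len(sample_idx), rel=1e-12)

    def test_independent_reintegration_agrees(self, theta_star, obs_clean,
                                              y0_alt):
        # slow-path oracle: re-integrate the driven secondary with the
        # generic Python integrator and accumulate the same average
        from repsync import rk2_integrate
        cfg = CostConfig(T=5.0, transient=1.0)
        spec = CouplingSpec()
        d = sync_distance(theta_star, obs_clean, spec, cfg, y0_alt)

        def drive(t):
            return np.array([np.interp(t, obs_clean.times,
                                       obs_clean.column(c))
                             for c in spec.observed_channels])

        def rhs(y, t, u):
            return secondary_rhs(y, theta_star, u, spec)

        traj = rk2_integrate(rhs, y0_alt, 0.01, cfg.total_time, drive=drive)
        stride = int(round(cfg.sample_step / 0.01))
        idx = np.arange(int(round(cfg.transient / 0.01)),
                        len(traj.times), stride)
        total = 0.0
        for k in idx:
            for c in spec.observed_channels:
                uo = np.interp(traj.times[k], obs_clean.times,
                               obs_clean.column(c))
                total += (uo - traj.states[k, c]) ** 2
        assert d == pytest.approx(total / len(idx), rel=1e-6)

    def test_distance_insensitive_to_secondary_start(self, theta_star,
                                                     obs_clean, y0_alt):
        d1 = sync_distance(theta_star, obs_clean, y0=default_initial_state())
        d2 = sync_distance(theta_star, obs_clean, y0=y0_alt)
        assert d1 > 0 and d2 > 0
        assert abs(d1 - d2) <= 0.1 * max(d1, d2) or max(d1, d2) < 1e-8

    def test_invalid_parameters_give_infinite_cost(self, obs_clean,
                                                   theta_star):
        assert sync_distance(theta_star.replace(n=-1.0), obs_clean) == np.inf

    def test_observation_window_must_cover_cost_window(self, theta_star):
        cfg_short = CostConfig(T=2.0, transient=0.0)
        obs = simulate_observations(theta_star, seed=0, cfg=cfg_short)
        with pytest.raises(ValueError, match="cover"):
            sync_distance(theta_star, obs, cfg=CostConfig(T=50.0))


class TestExtendedDistance:
    def test_requires_extended_channels(self, theta_star, obs_clean):
        with pytest.raises(ValueError, match="extended"):
            extended_distance(theta_star, obs_clean)

    def test_at_least_restricted_two_channel_distance(self, theta_star,
                                                      y0_alt):
        cfg = CostConfig(T=10.0, transient=5.0, extended=True)
        obs8 = simulate_observations(theta_star, seed=2, cfg=cfg)
        theta = theta_star.replace(beta=theta_star.beta * 1.05)
        d8 = extended_distance(theta, obs8, cfg=cfg, y0=y0_alt)
        d2 = _distance(theta, obs8, CouplingSpec(), cfg, y0_alt, 0.01,
                       CouplingSpec().observed_channels)
        assert d8 >= d2 - 1e-12

    def test_direct_summation_oracle(self, theta_star, y0_alt):
        from repsync import _core
        cfg = CostConfig(T=3.0, transient=1.0, extended=True)
        spec = CouplingSpec()
        obs8 = simulate_observations(theta_star, seed=2, cfg=cfg)
        d = extended_distance(theta_star, obs8, spec, cfg, y0_alt)
        dt = 0.01
        n_steps = int(round(cfg.total_time / dt))
        grid = np.arange(n_steps + 1) * dt
        u = np.column_stack([np.interp(grid, obs8.times, obs8.column(c))
                             for c in spec.observed_channels])
        stride = int(round(cfg.sample_step / dt))
        sample_idx = np.arange(int(round(cfg.transient / dt)),
                               n_steps + 1, stride, dtype=np.int64)
        samples, _, _ = _core.rk2_drive(
            np.asarray(y0_alt, float), theta_star.to_array(), dt, n_steps, u,
            np.array(spec.observed_channels, dtype=np.int64), spec.D,
            sample_idx, np.array(EXTENDED_CHANNELS, dtype=np.int64), False)
        total = 0.0
        for k in range(len(sample_idx)):
            for j, c in enumerate(EXTENDED_CHANNELS):
                uo = np.interp(sample_idx[k] * dt, obs8.times,
                               obs8.column(c))
                total += (uo - samples[k, j]) ** 2
        assert d == pytest.approx(total / len(sample_idx), rel=1e-12)


class TestNQE:
    def test_zero_at_truth(self, theta_star):
        assert all(v == 0 for v in nqe(theta_star, theta_star).values())

    def test_doubling_gives_one(self, theta_star):
        doubled = theta_star.replace(Q=2 * theta_star.Q)
        assert nqe(doubled, theta_star, which=["Q"])["Q"] == pytest.approx(1.0)

    def test_ten_percent_gives_one_hundredth(self, theta_star):
        off = theta_star.replace(eta=1.1 * theta_star.eta)
        assert nqe(off, theta_star, which=["eta"])["eta"] == pytest.approx(
            0.01, rel=1e-9)

    def test_zero_reference_rejected(self, theta_star):
        zero = theta_star.replace(Q=0.0)
        with pytest.raises(ZeroDivisionError):
            nqe(theta_star, zero, which=["Q"])


class TestObservationNoise:
    def test_zero_sigma_is_identity(self, obs_clean):
        same = add_observation_noise(obs_clean, 0.0, seed=1)
        np.testing.assert_array_equal(same.channels, obs_clean.channels)

    def test_seed_reproducible(self, obs_clean):
        a = add_observation_noise(obs_clean, 0.1, seed=7)
        b = add_observation_noise(obs_clean, 0.1, seed=7)
        np.testing.assert_array_equal(a.channels, b.channels)

    def test_empirical_variance_matches(self, theta_star):
        cfg = CostConfig(T=500.0, transient=0.0, sample_step=0.01)
        obs = simulate_observations(theta_star, seed=0, cfg=cfg)
        sigma = 0.3
        noisy = add_observation_noise(obs, sigma, seed=11)
        resid = (noisy.channels - obs.channels).ravel()
        assert resid.size >= 1e5
        assert np.var(resid) == pytest.approx(sigma ** 2, rel=0.05)

    def test_noise_floor_values(self):
        assert noise_floor(0.0) == 0.0
        assert noise_floor(0.1) == pytest.approx(0.02)
        with pytest.raises(ValueError):
            noise_floor(-0.1)


class TestSyncCost:
    def test_counts_evaluations_and_embeds_subset(self, theta_star,
                                                  obs_clean):
        cost = SyncCost(obs_clean, ("Q", "n"), base_theta=theta_star)
        v = cost([theta_star.Q, theta_star.n])
        assert cost.n_calls == 1
        assert v >= 0
        assert cost.theta([0.5, 3.0]) == theta_star.replace(Q=0.5, n=3.0)
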