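"""Reflected Euler-Maruyama engine against analytic moments and the SSA oracle."""

import numpy as np
import pytest
from scipy import stats as sstats

from bvrpop.markov import ChannelStateVector, steady_state_distribution
from bvrpop.sde import (
    SDEConfig,
    VoltageProtocol,
    project_simplex,
    simulate_channel_ode,
    simulate_channel_sde,
    simulate_channel_ssa,
    step_reflected_em,
)
from conftest import make_two_state


class TestProjection:
    def test_identity_on_simplex(self, rng):
        X = rng.dirichlet(np.ones(4), size=50)
        assert np.allclose(project_simplex(X), X, atol=1e-12)

    def test_projection_properties(self, rng):
        X = rng.normal(0.3, 1.0, size=(200, 5))
        P = project_simplex(X)
        assert np.all(P >= 0)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
        # projection is idempotent
        assert np.allclose(project_simplex(P), P, atol=1e-9)


class TestStepReflectedEM:
    def test_infinite_N_equals_explicit_euler(self, rng):
        scheme = make_two_state(2.0, 0.5)
        x = np.array([0.7, 0.3])
        cfg = SDEConfig(dt=0.01, N=np.inf)
        out = step_reflected_em(x, scheme, 0.0, 1e-4, cfg, rng)
        A = np.array([[-2.0, 0.5], [2.0, -0.5]])
        assert np.allclose(out.values, x + (A @ x) * cfg.dt, atol=1e-12)

    def test_absorbing_under_zero_intensity(self, rng):
        scheme = make_two_state(0.0, 1.0)
        cfg = SDEConfig(dt=0.01, N=100)
        out = step_reflected_em(np.array([1.0, 0.0]), scheme, 0.0, 1e-4, cfg, rng)
        assert np.allclose(out.values, [1.0, 0.0], atol=1e-5)

    def test_single_step_moments(self, rng):
        """Mean and variance of one EM increment follow the drift/noise law."""
        scheme = make_two_state(1.0, 1.0)
        cfg = SDEConfig(dt=0.01, N=100)
        x0 = np.array([0.5, 0.5])
        n = 10_000
        opens = np.empty(n)
        for k in range(n):
            opens[k] = step_reflected_em(x0, scheme, 0.0, 1e-4, cfg, rng).values[1]
        # drift vanishes at the symmetric point; var = (d1+d2) dt / N = 1e-4
        se_mean = np.sqrt(1e-4 / n)
        assert abs(opens.mean() - 0.5) < 3 * se_mean
        assert abs(opens.var() / 1e-4 - 1.0) < 0.05


class TestSimulateSDE:
    def test_stationary_mean_and_binomial_variance(self):
        scheme = make_two_state(2.0, 2.0)
        cfg = SDEConfig(dt=0.01, N=50, seed=5)
        traj = simulate_channel_sde(scheme, VoltageProtocol.constant(0.0, 10_000.0),
                                    cfg, output_stride=10)
        p = traj.open_fraction[len(traj.open_fraction) // 10:]
        assert abs(p.mean() - 0.5) < 0.02
        assert abs(p.var() / (0.25 / 50) - 1.0) < 0.15

    def test_identical_seed_identical_trajectory(self):
        scheme = make_two_state(1.0, 3.0)
        proto = VoltageProtocol.constant(0.0, 100.0)
        cfg = SDEConfig(dt=0.01, N=200, seed=42)
        t1 = simulate_channel_sde(scheme, proto, cfg)
        t2 = simulate_channel_sde(scheme, proto, cfg)
        assert np.array_equal(t1.states, t2.states)

    def test_large_N_matches_ode_relaxation(self):
        """N = 1e6 trajectory tracks the deterministic limit within 1%."""
        scheme = make_two_state(0.2, 0.2)
        proto = VoltageProtocol.constant(0.0, 50.0)
        x0 = np.array([1.0, 0.0])  # relax from fully closed toward 0.5
        cfg = SDEConfig(dt=0.01, N=1_000_000, seed=3)
        sde = simulate_channel_sde(scheme, proto, cfg, x0=x0, output_stride=10)
        ode = simulate_channel_ode(scheme, proto, x0=x0, output_dt=0.1)
        # the ODE oracle itself tracks the closed form
        ode_analytic = 0.5 * (1.0 - np.exp(-0.4 * ode.times))
        assert np.abs(ode.open_fraction - ode_analytic).max() < 1e-6
        analytic = 0.5 * (1.0 - np.exp(-0.4 * sde.times))
        err = np.abs(sde.open_fraction - analytic)
        assert err.max() < 0.01

    def test_boundedness_under_strong_noise(self):
        """1e6 reflected steps at N = 25 stay on the simplex."""
        scheme = make_two_state(1.0, 1.0)
        cfg = SDEConfig(dt=0.01, N=25, seed=11)
        traj = simulate_channel_sde(scheme,
                                    VoltageProtocol.constant(0.0, 10_000.0), cfg)
        assert np.all(traj.states >= -1e-12)
        assert np.all(traj.states <= 1 + 1e-12)
        assert np.allclose(traj.states.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_duration_protocol(self):
        scheme = make_two_state(1.0, 1.0)
        traj = simulate_channel_sde(scheme, VoltageProtocol.constant(0.0, 0.0),
                                    SDEConfig())
        assert len(traj.times) == 0

    def test_non_monotone_protocol_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            VoltageProtocol(np.array([0.0, 10.0, 5.0]),
                            np.array([-80.0, 0.0, -80.0]), 20.0)


class TestSSA:
    def test_single_channel_dwell_times_exponential(self):
        """N=1 occupancy alternates; dwell times are exponential (mean 1/rate)."""
        scheme = make_two_state(2.0, 2.0)
        traj = simulate_channel_ssa(scheme,
                                    VoltageProtocol.constant(0.0, 2000.0),
                                    N=1, seed=21, output_dt=0.005)
        s = traj.open_fraction
        assert set(np.unique(s)) <= {0.0, 1.0}
        switches = np.flatnonzero(np.diff(s) != 0)
        dwells = np.diff(traj.times[switches])
        assert len(dwells) > 1000
        assert abs(dwells.mean() - 0.5) < 0.05
        ks = sstats.kstest(dwells, "expon", args=(0, dwells.mean()))
        assert ks.pvalue > 0.01

    def test_ergodic_mean_matches_steady_state(self):
        scheme = make_two_state(1.0, 0.5)
        target = steady_state_distribution(scheme, 0.0).values[1]
        traj = simulate_channel_ssa(scheme,
                                    VoltageProtocol.constant(0.0, 20_000.0),
                                    N=10_000, seed=2)
        assert abs(traj.open_fraction.mean() / target - 1.0) < 0.01

    def test_zero_duration_protocol_empty(self):
        scheme = make_two_state(1.0, 1.0)
        traj = simulate_channel_ssa(scheme, VoltageProtocol.constant(0.0, 0.0),
                                    N=10, seed=0)
        assert len(traj.times) == 0

    def test_channel_guard(self):
        scheme = make_two_state(1.0, 1.0)
        with pytest.raises(ValueError, match="guard"):
            simulate_channel_ssa(scheme, VoltageProtocol.constant(0.0, 1.0),
                                 N=200_000, seed=0)


class TestConvergence:
    def test_halving_dt_within_monte_carlo_error(self):
        """Stationary variance is dt-insensitive at the working step size."""
        from bvrpop.sde import stationary_moments_sde

        scheme = make_two_state(0.5, 0.5)  # tau = 1 ms
        res = {}
        for dt in (0.01, 0.005):
            cfg = SDEConfig(dt=dt, N=100, seed=17)
            m, v, n = stationary_moments_sde(scheme, 0.0, cfg, t_total=2000.0,
                                             burn_in=100.0, n_chains=8)
            res[dt] = (v, n)
        v1, n1 = res[0.01]
        v2, _ = res[0.005]
        # effective sample count: samples 0.1 ms apart decorrelate over ~2 tau
        n_eff = n1 * 0.1 / 2.0
        mc_se_diff = v1 * np.sqrt(2.0) * np.sqrt(2.0 / n_eff)
        assert abs(v1 - v2) < 3 * mc_se_diff
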