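import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tslandscape import models, simulate
from tslandscape.models import dev_network, dev_noise_covariance, toy_drift
from tslandscape.simulate import (
    Ensemble,
    IntegrationError,
    ParameterSchedule,
    SimConfig,
    cle_ensemble,
    cle_integrate,
    euler_maruyama,
    run_ensemble,
    sample_box,
    ssa_gillespie,
    toy_em_drift,
    toy_ensemble,
)


class TestParameterSchedule:
    def test_constant(self):
        s = ParameterSchedule.constant("L", 50.0)
        assert s.value(0.0) == 50.0 and s.value(1e6) == 50.0

    def test_linear_ramp_and_hold(self):
        s = ParameterSchedule.linear("beta", -0.5, 0.5, 1.0)
        assert s.value(0.0) == -0.5
        assert s.value(0.25) == pytest.approx(-0.25)
        assert s.value(1.0) == 0.5
        assert s.value(3.0) == 0.5  # held after the ramp

    def test_step(self):
        s = ParameterSchedule.step("L", 200.0, 0.0, at=10.0)
        assert s.value(9.99) == 200.0 and s.value(10.0) == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            ParameterSchedule(name="L", mode="exponential")
        with pytest.raises(ValueError):
            ParameterSchedule(name="L", mode="linear", start=0.0, end=1.0,
                              duration=0.0)
        with pytest.raises(ValueError):
            ParameterSchedule(name="L", mode="linear", start=0.0)


class TestSimConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimConfig(t_end=1.0, dt=0.2, record_interval=0.1)
        with pytest.raises(ValueError):
            SimConfig(t_end=1.0, dt=0.03, record_interval=0.1)  # non-integral
        with pytest.raises(ValueError):
            SimConfig(t_end=0.0, dt=0.1, record_interval=0.1)

    def test_grid(self):
        cfg = SimConfig(t_end=1.0, dt=0.01, record_interval=0.25)
        np.testing.assert_allclose(cfg.time_grid(), [0, 0.25, 0.5, 0.75, 1.0])


class TestEulerMaruyama:
    def test_deterministic_limit_reaches_well(self, toy_params):
        # independent oracle: adaptive ODE integration of the same drift
        cfg = SimConfig(t_end=30.0, dt=1e-3, record_interval=0.5, seed=0)
        traj = euler_maruyama(toy_em_drift(toy_params), 0.0, [2.0, 0.0], None, cfg)
        sol = solve_ivp(lambda t, x: toy_drift(x, toy_params), (0, 30.0),
                        [2.0, 0.0], rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(traj.states[-1], sol.y[:, -1], atol=1e-3)
        well = models.toy_fixed_x1_roots(toy_params)[-1]
        assert abs(traj.states[-1, 0] - well) < 1e-3

    def test_seeded_determinism(self, toy_params):
        cfg = SimConfig(t_end=1.0, dt=1e-3, record_interval=0.01, seed=42)
        a = euler_maruyama(toy_em_drift(toy_params), toy_params.sigma,
                           [1.0, 0.0], None, cfg)
        b = euler_maruyama(toy_em_drift(toy_params), toy_params.sigma,
                           [1.0, 0.0], None, cfg)
        np.testing.assert_array_equal(a.states, b.states)

    def test_wiener_increment_variance(self, toy_params):
        # drift suppressed via the test hook; single dt step, huge ensemble
        cfg = SimConfig(t_end=1e-3, dt=1e-3, record_interval=1e-3, seed=0)
        ens = toy_ensemble(toy_params, [0.0, 0.0], None, cfg, n=100_000,
                           base_seed=3, drift=lambda x, u: 0.0 * x)
        var = ens.states[:, 1, :].var(axis=0, ddof=1)
        target = toy_params.sigma**2 * 1e-3
        np.testing.assert_allclose(var, target, rtol=0.05)

    def test_divergence_reported(self, toy_params):
        cfg = SimConfig(t_end=2.0, dt=0.5, record_interval=0.5, seed=0)
        exploding = lambda x, u: x * 1e200
        with pytest.raises(IntegrationError, match="member|step"):
            euler_maruyama(exploding, 0.0, [1.0, 1.0], None, cfg)

    def test_no_nan_in_output(self, toy_params):
        cfg = SimConfig(t_end=5.0, dt=1e-3, record_interval=0.05, seed=7)
        traj = euler_maruyama(toy_em_drift(toy_params), toy_params.sigma,
                              [1.0, 0.0], None, cfg)
        assert np.all(np.isfinite(traj.states))
        np.testing.assert_allclose(traj.times, np.arange(101) * 0.05)


class TestSSA:
    def test_no_enabled_reactions_constant_zero(self, dev_params):
        p = dev_params.replace(k0=0, k1=0, k2=0, k3=0, k6=0, k7=0, k9=0,
                               k10=0, k11=0, k12=0, k14=0)
        cfg = SimConfig(t_end=50.0, dt=1.0, record_interval=5.0, seed=0)
        traj = ssa_gillespie(dev_network(p), [0, 0, 0, 0], None, cfg)
        np.testing.assert_array_equal(traj.states, 0.0)

    def test_pure_death_matches_closed_form(self, dev_params):
        p = dev_params.replace(k0=0, k1=0, k2=0, k3=0, k6=0, k7=0, k9=0,
                               k10=0, k11=0, k12=0, k14=0)
        net = dev_network(p)
        cfg = SimConfig(t_end=100.0, dt=1.0, record_interval=25.0, seed=0)

        def one(x0, sched, c):
            return ssa_gillespie(net, x0, sched, c)

        ens = run_ensemble(one, [100, 0, 0, 0], None, cfg, n=400, base_seed=7)
        N = ens.column("N")
        for i, t in enumerate(ens.times[1:], start=1):
            target = 100 * np.exp(-p.kd * t)
            se = N[:, i].std(ddof=1) / np.sqrt(ens.n_members)
            assert abs(N[:, i].mean() - target) < 3 * se

    def test_states_are_nonnegative_integers(self, dev_params):
        cfg = SimConfig(t_end=100.0, dt=1.0, record_interval=2.0, seed=11)
        traj = ssa_gillespie(dev_network(dev_params), [70, 6, 111, 1], None, cfg)
        assert np.all(traj.states >= 0)
        np.testing.assert_array_equal(traj.states, np.round(traj.states))

    def test_seeded_determinism(self, dev_params):
        cfg = SimConfig(t_end=50.0, dt=1.0, record_interval=5.0, seed=5)
        net = dev_network(dev_params)
        a = ssa_gillespie(net, [70, 6, 111, 1], None, cfg)
        b = ssa_gillespie(net, [70, 6, 111, 1], None, cfg)
        np.testing.assert_array_equal(a.states, b.states)

    def test_noninteger_initial_state_rejected(self, dev_params):
        cfg = SimConfig(t_end=1.0, dt=1.0, record_interval=1.0, seed=0)
        with pytest.raises(ValueError):
            ssa_gillespie(dev_network(dev_params), [1.5, 0, 0, 0], None, cfg)

    def test_schedule_is_honoured(self, dev_params):
        # LIF withdrawal destabilizes the stem state: the ramped ensemble
        # must end with substantially less Nanog than the high-L control
        net = dev_network(dev_params)
        cfg = SimConfig(t_end=800.0, dt=1.0, record_interval=200.0, seed=0)
        ramp = ParameterSchedule.linear("L", 150.0, 0.0, 400.0)

        def with_ramp(x0, sched, c):
            return ssa_gillespie(net, x0, ramp, c)

        def const_high(x0, sched, c):
            return ssa_gillespie(dev_network(dev_params.replace(L=150.0)),
                                 x0, None, c)

        x0 = [72, 6, 111, 1]
        ramped = run_ensemble(with_ramp, x0, None, cfg, n=30, base_seed=13)
        control = run_ensemble(const_high, x0, None, cfg, n=30, base_seed=13)
        assert (ramped.column("N")[:, -1].mean()
                < control.column("N")[:, -1].mean() - 10)


class TestCLE:
    def test_stationary_at_fixed_point_without_noise(self, dev_params, dev_branches_L50):
        p = dev_params.replace(L=50.0)
        x0 = dev_branches_L50["stem-cell"].location
        cfg = SimConfig(t_end=10.0, dt=0.1, record_interval=1.0, seed=0)
        traj = cle_integrate(dev_network(p), x0, None, cfg, noise_scale=0.0)
        drift_free = np.abs(traj.states - x0).max()
        assert drift_free < 1e-6

    def test_schedule_matches_time_varying_ode_oracle(self, dev_params):
        # noiseless CLE with an L-ramp must follow the non-autonomous rate
        # equations (independent adaptive integration)
        from scipy.integrate import solve_ivp

        sched = ParameterSchedule.linear("L", 150.0, 0.0, 300.0)
        cfg = SimConfig(t_end=300.0, dt=0.25, record_interval=50.0, seed=0)
        x0 = np.array([72.0, 6.0, 111.0, 1.0])
        traj = cle_integrate(dev_network(dev_params), x0, sched, cfg,
                             noise_scale=0.0)
        sol = solve_ivp(
            lambda t, x: models.dev_drift(
                np.clip(x, 0, None),
                dev_params.replace(L=float(sched.value(t)))),
            (0.0, 300.0), x0, rtol=1e-9, atol=1e-10)
        np.testing.assert_allclose(traj.states[-1], sol.y[:, -1], atol=0.05)

    def test_one_step_increment_covariance(self, dev_params):
        x0 = np.array([70.0, 6.0, 111.0, 1.0])
        dt = 0.5
        cfg = SimConfig(t_end=dt, dt=dt, record_interval=dt, seed=0)
        ens = cle_ensemble(dev_params, x0, None, cfg, n=100_000, base_seed=42)
        incr = ens.states[:, 1, :] - x0
        cov = np.cov(incr.T)
        target = dev_noise_covariance(x0, dev_params) * dt
        np.testing.assert_allclose(np.diag(cov), np.diag(target), rtol=0.05)
        # off-diagonals are exactly zero in law; allow MC noise
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 0.05 * np.diag(target).max()

    def test_clamp_policy(self, dev_params):
        # start at zero copy numbers: noise would go negative without clamping
        cfg = SimConfig(t_end=50.0, dt=1.0, record_interval=1.0, seed=3)
        traj = cle_integrate(dev_network(dev_params.replace(L=0.0)),
                             [0.0, 0.0, 0.0, 0.0], None, cfg)
        assert np.all(traj.states >= 0)
        assert traj.meta["clamps"] >= 0

    def test_matches_ssa_moments_at_stem_state(self, dev_params):
        # documented approximation check: means within 10%, variances within
        # 25%, with a 1-copy absolute floor for near-zero species where the
        # Langevin approximation is known to break down
        p = dev_params.replace(L=200.0)
        x0 = np.array([73.0, 7.0, 111.0, 0.0])
        net = dev_network(p)
        cfg = SimConfig(t_end=150.0, dt=0.5, record_interval=150.0, seed=0)

        def one(x0_, sched, c):
            return ssa_gillespie(net, np.round(x0_), sched, c)

        ssa = run_ensemble(one, x0, None, cfg, n=1000, base_seed=31)
        cle = cle_ensemble(p, x0, None, cfg, n=1000, base_seed=32)
        fs, fc = ssa.states[:, -1, :], cle.states[:, -1, :]
        for j in range(4):
            ms, mc = fs[:, j].mean(), fc[:, j].mean()
            vs, vc = fs[:, j].var(ddof=1), fc[:, j].var(ddof=1)
            assert abs(ms - mc) <= max(0.10 * max(ms, mc), 1.0)
            assert abs(vs - vc) <= max(0.25 * max(vs, vc), 1.0)


class TestEnsembles:
    def test_reproducible_as_a_whole(self, toy_params):
        cfg = SimConfig(t_end=0.5, dt=1e-3, record_interval=0.1, seed=0)
        a = toy_ensemble(toy_params, [1.0, 0.0], None, cfg, n=5, base_seed=9)
        b = toy_ensemble(toy_params, [1.0, 0.0], None, cfg, n=5, base_seed=9)
        np.testing.assert_array_equal(a.states, b.states)
        np.testing.assert_array_equal(a.member_seeds, b.member_seeds)

    def test_batched_equals_looped(self, toy_params):
        sched = ParameterSchedule.linear("beta", -0.5, 0.5, 1.0)
        cfg = SimConfig(t_end=0.5, dt=1e-3, record_interval=0.1, seed=0)
        batched = toy_ensemble(toy_params, [1.2, 0.0], sched, cfg, n=4, base_seed=9)

        def one(x0, sch, c):
            return euler_maruyama(toy_em_drift(toy_params), toy_params.sigma,
                                  x0, sch, c)

        looped = run_ensemble(one, [1.2, 0.0], sched, cfg, n=4, base_seed=9)
        np.testing.assert_array_equal(batched.states, looped.states)

    def test_cle_batched_equals_looped(self, dev_params):
        cfg = SimConfig(t_end=5.0, dt=1.0, record_interval=1.0, seed=0)
        x0 = np.array([70.0, 6.0, 111.0, 1.0])
        batched = cle_ensemble(dev_params, x0, None, cfg, n=3, base_seed=17)

        def one(x0_, sched, c):
            return cle_integrate(dev_network(dev_params), x0_, sched, c)

        looped = run_ensemble(one, x0, None, cfg, n=3, base_seed=17)
        np.testing.assert_array_equal(batched.states, looped.states)

    def test_member_failure_reports_index_and_seed(self, toy_params):
        cfg = SimConfig(t_end=1.0, dt=0.5, record_interval=0.5, seed=0)

        def bad(x0, sched, c):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="member 0 \\(seed"):
            run_ensemble(bad, [0.0, 0.0], None, cfg, n=3, base_seed=1)

    def test_needs_two_members(self, toy_params):
        cfg = SimConfig(t_end=1.0, dt=0.5, record_interval=0.5, seed=0)
        with pytest.raises(ValueError):
            toy_ensemble(toy_params, [0.0, 0.0], None, cfg, n=1, base_seed=0)

    def test_member_view(self, toy_params):
        cfg = SimConfig(t_end=0.2, dt=0.1, record_interval=0.1, seed=0)
        ens = toy_ensemble(toy_params, [1.0, 0.0], None, cfg, n=3, base_seed=4)
        m1 = ens.member(1)
        np.testing.assert_array_equal(m1.states, ens.states[1])
        assert m1.seed == ens.member_seeds[1]


class TestTransitoryToyEnsemble:
    def test_variance_signature(self):
        from tslandscape.experiments import toy_transitory_ensemble
        from tslandscape.landscape import variance_timeseries

        ens = toy_transitory_ensemble(n=300, base_seed=5)
        var = variance_timeseries(ens)
        v1 = var["var_x1"].to_numpy()
        v2 = var["var_x2"].to_numpy()
        assert v1.max() > v1[0] and v1.max() > v1[-1]
        assert 0 < np.argmax(v1) < len(v1) - 1
        assert v2.max() / v2.min() < 3.0


class TestIrreversibility:
    def test_no_return_from_differentiated_state(self, dev_params, dev_branches_L50):
        p = dev_params.replace(L=200.0)
        x0 = np.round(dev_branches_L50["differentiated"].location)
        net = dev_network(p)
        cfg = SimConfig(t_end=1500.0, dt=1.0, record_interval=100.0, seed=0)

        def one(x0_, sched, c):
            return ssa_gillespie(net, x0_, sched, c)

        ens = run_ensemble(one, x0, None, cfg, n=200, base_seed=77)
        finals = ens.states[:, -1, :]
        regained = (finals[:, 0] > 40) & (finals[:, 3] < 20)
        assert regained.sum() == 0


class TestSampleBox:
    def test_within_ranges_and_deterministic(self):
        ranges = [(60, 100), (0, 12), (90, 130), (0, 16)]
        a = sample_box(ranges, 500, seed=3)
        b = sample_box(ranges, 500, seed=3)
        np.testing.assert_array_equal(a, b)
        for j, (lo, hi) in enumerate(ranges):
            assert a[:, j].min() >= lo and a[:, j].max() <= hi

    def test_mean_matches_midpoint(self):
        ranges = [(0.0, 10.0), (-4.0, 4.0)]
        s = sample_box(ranges, 10_000, seed=5)
        for j, (lo, hi) in enumerate(ranges):
            mid = 0.5 * (lo + hi)
            se = (hi - lo) / np.sqrt(12 * s.shape[0])
            assert abs(s[:, j].mean() - mid) < 3 * se

    def test_integer_mode(self):
        s = sample_box([(0, 5)], 100, seed=1, integer=True)
        np.testing.assert_array_equal(s, np.round(s))

    def test_inverted_range(self):
        with pytest.raises(ValueError):
            sample_box([(1.0, 0.0)], 10, seed=0)
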