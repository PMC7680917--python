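"""Single-oscillator and network dynamics: illumination, fixed points,
RK4 integration, maxima counting and period measurement."""

import numpy as np
import pytest

from oscnet import (IlluminationSchedule, IntegratorConfig, NetworkSpec,
                    NoOscillationError, OregonatorParams, PeakConfig,
                    SimulationError, Trajectory, count_maxima, illumination,
                    integrate, measure_period, peak_times, rhs, steady_state)
from oscnet.dynamics import integrate_counts

from conftest import fast_cfg


class TestIllumination:
    def test_saturated_before_switch_off(self):
        sched = IlluminationSchedule(t_ilum=[4.0])
        assert illumination(0.0, 4.0, sched) == pytest.approx(0.2001, abs=1e-12)

    def test_half_height_at_switch_off(self):
        sched = IlluminationSchedule(t_ilum=[4.0])
        assert illumination(4.0, 4.0, sched) == pytest.approx(0.1001, abs=1e-15)

    def test_long_time_floor(self):
        # light off long after t_ilum: phi approaches 0.0001
        sched = IlluminationSchedule(t_ilum=[1.0])
        assert illumination(1e3, 1.0, sched) == pytest.approx(0.0001, rel=1e-9)

    def test_monotone_non_increasing(self):
        sched = IlluminationSchedule(t_ilum=[3.0])
        t = np.linspace(0.0, 20.0, 2001)
        phi = illumination(t, 3.0, sched)
        assert np.all(np.diff(phi) <= 0)
        assert np.all(phi > 0)

    def test_validation(self):
        with pytest.raises(ValueError):
            IlluminationSchedule(t_ilum=[-1.0])
        with pytest.raises(ValueError):
            IlluminationSchedule(t_ilum=[1.0], offset=0.9)


class TestRhs:
    def test_fraction_term_vanishes_at_u_equals_q(self, params):
        net = NetworkSpec(n_osc=3, alpha=0.0, beta=0.0)
        sched = IlluminationSchedule(t_ilum=[10.0, 10.0, 10.0])
        q = params.q_const
        u = np.full(3, q)
        du, dv = rhs(u, u, 0.0, params, net, sched)
        expect = (q - q * q) / params.epsilon
        assert du == pytest.approx([expect] * 3, rel=1e-12)
        assert np.all(du > 0)

    def test_symmetric_state_coupling_cancels(self, params):
        # at a uniform state the exchange terms cancel, leaving pure decay
        a = 0.3
        sched = IlluminationSchedule(t_ilum=[5.0, 5.0, 5.0])
        coupled = NetworkSpec(n_osc=3, alpha=0.849, beta=0.251)
        isolated = NetworkSpec(n_osc=3, alpha=0.849, beta=0.0)
        u = np.full(3, a)
        v = np.full(3, 0.1)
        du_c, _ = rhs(u, v, 0.0, params, coupled, sched)
        du_i, _ = rhs(u, v, 0.0, params, isolated, sched)
        assert du_c == pytest.approx(du_i, rel=1e-12)

    def test_uncoupled_oscillators_independent(self, params):
        net = NetworkSpec(n_osc=3, alpha=0.2, beta=0.0)
        sched = IlluminationSchedule(t_ilum=[5.0, 5.0, 5.0])
        u = np.array([0.1, 0.2, 0.3])
        v = np.array([0.05, 0.1, 0.2])
        du, _ = rhs(u, v, 1.0, params, net, sched)
        u2 = u.copy()
        u2[0] = 0.9  # perturbing one oscillator must not touch the others
        du2, _ = rhs(u2, v, 1.0, params, net, sched)
        assert du[1:] == pytest.approx(du2[1:], rel=0, abs=0)

    def test_rejects_domain_violation(self, params):
        net = NetworkSpec(n_osc=1)
        sched = IlluminationSchedule(t_ilum=[5.0])
        with pytest.raises(SimulationError):
            rhs(np.array([-2 * params.q_const]), np.array([0.1]), 0.0,
                params, net, sched)


class TestSteadyState:
    def test_illuminated_rest_state(self, params):
        u, v = steady_state(0.2001, params, alpha=0.0)
        assert u == v
        assert round(u, 4) == 0.0002  # printed to one significant figure

    def test_against_bisection_oracle(self, params):
        # frozen values from a 200-iteration bisection on the same equation
        assert steady_state(0.2001, params, 0.0)[0] == pytest.approx(
            0.00020040048019095313, abs=1e-12)
        assert steady_state(0.2001, params, 0.849)[0] == pytest.approx(
            0.000200332295460643, abs=1e-12)

    def test_decay_shifts_root_by_under_two_percent(self, params):
        u0 = steady_state(0.2001, params, 0.0)[0]
        u1 = steady_state(0.2001, params, 0.849)[0]
        assert abs(u1 - u0) / u0 < 0.02

    def test_strong_light_pins_activator_near_q(self, params):
        u, _ = steady_state(10.0, params, 0.0)
        assert u < params.q_const * 1.01

    def test_rhs_residual_small(self, params):
        alpha = 0.849
        u, v = steady_state(0.2001, params, alpha)
        net = NetworkSpec(n_osc=1, alpha=alpha)
        sched = IlluminationSchedule(t_ilum=[50.0])  # phi(0) = 0.2001
        du, dv = rhs(np.array([u]), np.array([v]), 0.0, params, net, sched)
        assert abs(du[0]) < 1e-9 and abs(dv[0]) < 1e-9


class TestIntegrate:
    def test_quiescent_then_excited(self, params, single_osc, peaks):
        # inhibited rest below t_ilum=4, large excursions afterwards
        sched = IlluminationSchedule(t_ilum=[4.0])
        traj = integrate(params, single_osc, sched, fast_cfg(20.0))
        before = traj.u[traj.times < 4.0, 0]
        assert np.all(np.abs(before - 2e-4) < 0.1 * 2e-4)
        assert traj.u.max() > 0.05

    def test_illuminated_throughout_stays_at_rest(self, params, single_osc):
        sched = IlluminationSchedule(t_ilum=[20.0])
        cfg = fast_cfg(20.0)
        traj = integrate(params, single_osc, sched, cfg)
        assert np.all(traj.u < 0.001)

    def test_trajectory_invariants(self, params, single_osc):
        sched = IlluminationSchedule(t_ilum=[4.0])
        cfg = fast_cfg(20.0)
        traj = integrate(params, single_osc, sched, cfg)
        assert traj.times[0] == 0.0
        assert traj.times[-1] == pytest.approx(20.0, abs=cfg.h * cfg.store_stride)
        assert np.all(np.diff(traj.times) > 0)
        assert np.isfinite(traj.u).all() and np.isfinite(traj.v).all()
        assert traj.u.min() > -1e-6

    def test_rk4_order_of_convergence(self, params, single_osc):
        # halving the step shrinks stored differences by >= 8x (order >= 3)
        sched = IlluminationSchedule(t_ilum=[4.0])
        runs = {}
        for h in (1e-3, 5e-4, 2.5e-4):
            cfg = IntegratorConfig(t_max=20.0, h=h, store_stride=round(0.1 / h))
            runs[h] = integrate(params, single_osc, sched, cfg)
        d1 = np.max(np.abs(runs[1e-3].u - runs[5e-4].u))
        d2 = np.max(np.abs(runs[5e-4].u - runs[2.5e-4].u))
        assert d1 / d2 >= 8.0

    def test_halved_step_agrees_closely(self, params, single_osc):
        sched = IlluminationSchedule(t_ilum=[4.0])
        cfg1 = IntegratorConfig(t_max=20.0, h=1e-4, store_stride=1000)
        cfg2 = IntegratorConfig(t_max=20.0, h=5e-5, store_stride=2000)
        t1 = integrate(params, single_osc, sched, cfg1)
        t2 = integrate(params, single_osc, sched, cfg2)
        assert np.max(np.abs(t1.u - t2.u)) < 1e-6

    def test_confinement_under_illumination(self, params, single_osc, peaks):
        sched = IlluminationSchedule(t_ilum=[8.0])
        traj = integrate(params, single_osc, sched, fast_cfg(20.0))
        q = params.q_const
        lit = traj.times < 7.5  # phi still ~0.2 here
        assert np.all(traj.u[lit, 0] > q / 2)
        assert np.all(traj.u[lit, 0] < 10 * q)
        above = traj.times[traj.u[:, 0] > peaks.height_threshold]
        assert above.size == 0 or above.min() > 8.0

    def test_permutation_equivariance(self, params):
        net = NetworkSpec(n_osc=3, alpha=0.849, beta=0.251)
        til = np.array([4.0, 7.0, 10.0])
        perm = np.array([2, 0, 1])
        cfg = fast_cfg(15.0)
        t_a = integrate(params, net, IlluminationSchedule(t_ilum=til), cfg)
        t_b = integrate(params, net,
                        IlluminationSchedule(t_ilum=til[perm]), cfg)
        assert np.array_equal(t_a.u[:, perm], t_b.u)
        assert np.array_equal(t_a.v[:, perm], t_b.v)

    def test_identical_schedules_stay_identical(self, params):
        net = NetworkSpec(n_osc=3, alpha=0.849, beta=0.251)
        sched = IlluminationSchedule(t_ilum=[5.0, 5.0, 5.0])
        traj = integrate(params, net, sched, fast_cfg(15.0))
        assert np.array_equal(traj.u[:, 0], traj.u[:, 1])
        assert np.array_equal(traj.u[:, 0], traj.u[:, 2])

    def test_batch_counts_match_trajectory_counts(self, params, peaks):
        # the on-the-fly counter must agree with counting stored trajectories
        net = NetworkSpec(n_osc=3, alpha=0.849, beta=0.251)
        rng = np.random.default_rng(5)
        til = 3.78 + 8.32 * rng.random((12, 3))
        cfg = fast_cfg(20.23)
        u0 = np.full((12, 3), steady_state(0.2001, params, net.alpha)[0])
        counts, status = integrate_counts(params, net, til, cfg, peaks,
                                          u0, u0.copy())
        assert np.all(status == 0)
        for b in range(12):
            traj = integrate(params, net,
                             IlluminationSchedule(t_ilum=til[b]), cfg,
                             init=(u0[b], u0[b].copy()))
            for j in range(3):
                assert counts[b, j] == count_maxima(traj, j, peaks)

    def test_csv_round_trip(self, params, single_osc, tmp_path):
        sched = IlluminationSchedule(t_ilum=[4.0])
        traj = integrate(params, single_osc, sched, fast_cfg(5.0))
        path = tmp_path / "traj.csv"
        traj.to_csv(path, metadata={"h": 1e-3})
        back = Trajectory.from_csv(path)
        assert np.allclose(back.u, traj.u)
        assert (tmp_path / "traj.json").exists()


class TestCountMaxima:
    def _traj(self, series):
        x = np.asarray(series, dtype=float)[:, None]
        return Trajectory(times=np.arange(len(series), dtype=float),
                          u=x, v=x.copy())

    def test_constant_series(self, peaks):
        assert count_maxima(self._traj([0.3] * 10), 0, peaks) == 0

    def test_interior_peaks_only(self, peaks):
        # peaks at ends are never counted
        assert count_maxima(self._traj([0.9, 0.1, 0.8, 0.1, 0.9]), 0, peaks) == 1

    def test_threshold_filters_small_peaks(self, peaks):
        assert count_maxima(self._traj([0.0, 0.04, 0.0, 0.4, 0.0]), 0, peaks) == 1

    def test_plateau_counted_once(self, peaks):
        assert count_maxima(self._traj([0.0, 0.5, 0.5, 0.0]), 0, peaks) == 1


class TestMeasurePeriod:
    def test_free_running_period_near_printed_value(self, params):
        cfg = IntegratorConfig(t_max=200.0, h=1e-3, store_stride=10)
        per = measure_period(params, 0.849, 0.0001, cfg)
        assert per == pytest.approx(10.8, rel=0.02)

    def test_window_stability(self, params):
        cfg1 = IntegratorConfig(t_max=200.0, h=1e-3, store_stride=10)
        cfg2 = IntegratorConfig(t_max=400.0, h=1e-3, store_stride=10)
        p1 = measure_period(params, 0.849, 0.0001, cfg1)
        p2 = measure_period(params, 0.849, 0.0001, cfg2)
        assert abs(p1 - p2) / p1 < 0.01

    def test_strong_illumination_suppresses_oscillation(self, params):
        cfg = IntegratorConfig(t_max=200.0, h=1e-3, store_stride=10)
        with pytest.raises(NoOscillationError):
            measure_period(params, 0.849, 0.2001, cfg)
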