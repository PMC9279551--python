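"""Stochastic Runge-Kutta integration of the delayed network equations."""

import math

import numpy as np
import pytest

from mlsisr.coupling import NetworkSpec, SynapseSpec
from mlsisr.integrate import (
    BlowUpError,
    HistoryBuffer,
    SimGrid,
    delayed_value,
    integrate,
    integrate_reference,
)
from mlsisr.spikes import detect_spikes


class TestHistoryBuffer:
    def setup_method(self):
        self.buf = HistoryBuffer(1, depth=8, dt=0.5, initial_v=np.array([2.0]))

    def test_lag_zero_is_current(self):
        self.buf.push(np.array([3.0]))
        assert self.buf.lookup(0, 0.0) == 3.0

    def test_pre_start_returns_initial(self):
        self.buf.push(np.array([3.0]))
        assert self.buf.lookup(0, 2.0) == 2.0  # before start: constant history

    def test_exact_grid_lag(self):
        for x in (3.0, 4.0, 5.0):
            self.buf.push(np.array([x]))
        assert self.buf.lookup(0, 1.0) == 3.0  # two steps back

    def test_linear_interpolation(self):
        for x in (3.0, 4.0):
            self.buf.push(np.array([x]))
        assert self.buf.lookup(0, 0.25) == pytest.approx(3.5)

    def test_lag_beyond_depth_raises(self):
        with pytest.raises(ValueError):
            delayed_value(self.buf, 100.0)


class TestDeterministic:
    def test_equilibrium_invariance(self, fixed_point):
        spec = NetworkSpec.single_neuron()
        grid = SimGrid(dt=0.008, t_total=200.0, n_realizations=1, seed=0)
        x0 = np.array([[fixed_point.v_e, fixed_point.w_e]])
        traj = integrate(spec, grid, initial=x0, record_stride=1)
        assert abs(traj.v[-1, 0] - fixed_point.v_e) < 1e-6
        assert abs(traj.w[-1, 0] - fixed_point.w_e) < 1e-6

    def test_delayed_linear_system_vs_step_halving(self):
        # dv/dt = -v(t-1), v = 1 on [-1, 0]; exact v(1) = 0, v(2) = -1/2.
        # On [0, 1] the delayed value is the constant history, so the scheme
        # is exact; past t = 1 the held-delay treatment converges at first
        # order, so step halving must halve the error.
        def drift(states, hist, t):
            out = np.zeros_like(states)
            out[0, 0] = -hist(0, 1.0)
            return out

        x0 = np.array([[1.0, 0.0]])
        v1 = {}
        v2 = {}
        for dt in (0.01, 0.005, 0.0025):
            n = int(round(2.0 / dt))
            _, path = integrate_reference(drift, x0, dt, n, max_lag=1.0)
            v1[dt] = path[int(round(1.0 / dt)), 0, 0]
            v2[dt] = path[-1, 0, 0]
        for dt in v1:
            assert v1[dt] == pytest.approx(0.0, abs=1e-12)
        assert abs(v2[0.005] - v2[0.0025]) <= 1e-4 + abs(v2[0.01] - v2[0.005]) / 2
        err = {dt: abs(v + 0.5) for dt, v in v2.items()}
        assert err[0.01] / err[0.005] == pytest.approx(2.0, rel=0.15)
        assert err[0.0025] == pytest.approx(0.0, abs=2e-3)

    def test_deterministic_convergence_is_second_order(self):
        # exponential decay: global error of the two-stage scheme ~ dt^2
        def drift(states, hist, t):
            return -states

        x0 = np.array([[1.0, 1.0]])
        errs = []
        for dt in (0.2, 0.1):
            n = int(round(2.0 / dt))
            _, path = integrate_reference(drift, x0, dt, n)
            errs.append(abs(path[-1, 0, 0] - math.exp(-2.0)))
        ratio = errs[0] / errs[1]
        assert 3.3 < ratio < 4.7

    def test_kernel_matches_reference_integrator(self, fixed_point):
        # coupled delayed motif, sigma = 0: compiled kernel vs plain-numpy path
        from mlsisr.coupling import assemble_drift

        spec = NetworkSpec.motif("C3", SynapseSpec("chemical", 0.8, 1.0, "inhibitory"))
        x0 = np.array([[fixed_point.v_e + 0.3, fixed_point.w_e]] * 3)
        x0[1, 0] -= 0.1
        dt, t_end = 0.008, 40.0
        grid = SimGrid(dt=dt, t_total=t_end, t_transient=0.0, n_realizations=1, seed=0)
        traj = integrate(spec, grid, initial=x0, record_stride=1)
        _, path = integrate_reference(
            assemble_drift(spec), x0, dt, grid.n_steps, max_lag=1.0
        )
        assert np.allclose(traj.v, path[1:, :, 0], atol=1e-9)
        assert np.allclose(traj.w, path[1:, :, 1], atol=1e-9)


class TestStochastic:
    def test_ou_stationary_variance(self):
        # dv = -v dt + s dW: Var = s^2/2; estimate within 3 standard errors
        def drift(states, hist, t):
            return np.column_stack([-states[:, 0], np.zeros(len(states))])

        s, dt, t_end = 0.5, 0.01, 4000.0
        n = int(t_end / dt)
        rng = np.random.default_rng(11)
        noise = rng.standard_normal((n, 1))
        _, path = integrate_reference(
            drift, np.zeros((1, 2)), dt, n, sigma=np.array([s]), noise=noise
        )
        v = path[int(50 / dt):, 0, 0]
        var = v.var()
        target = s**2 / 2
        n_eff = t_end / 2.0  # decorrelation time = 2/theta
        se = target * math.sqrt(2.0 / n_eff)
        assert abs(var - target) < 3 * se

    def test_determinism_bit_for_bit(self):
        spec = NetworkSpec.single_neuron(noise_sigma=0.01)
        grid = SimGrid(dt=0.008, t_total=2000.0, n_realizations=1, seed=42)
        a = integrate(spec, grid, realization=3, record_stride=10)
        b = integrate(spec, grid, realization=3, record_stride=10)
        assert np.array_equal(a.v, b.v)
        assert np.array_equal(a.spike_times[0], b.spike_times[0])

    def test_realizations_differ(self):
        spec = NetworkSpec.single_neuron(noise_sigma=0.01)
        grid = SimGrid(dt=0.008, t_total=2000.0, n_realizations=1, seed=42)
        a = integrate(spec, grid, realization=0, record_stride=0)
        b = integrate(spec, grid, realization=1, record_stride=0)
        assert not np.array_equal(a.spike_times[0], b.spike_times[0])

    def test_online_spike_detection_matches_offline(self):
        spec = NetworkSpec.single_neuron(noise_sigma=0.02)
        grid = SimGrid(dt=0.008, t_total=4000.0, n_realizations=1, seed=5)
        traj = integrate(spec, grid, record_stride=1)
        offline = detect_spikes(traj.t, traj.v[:, 0])
        online = traj.spike_times[0]
        assert len(offline) == len(online) >= 3
        assert np.allclose(offline.times, online, atol=grid.dt)

    def test_blowup_detected(self):
        spec = NetworkSpec.single_neuron(noise_sigma=5.0)  # absurd noise
        grid = SimGrid(dt=0.008, t_total=500.0, n_realizations=1, seed=1)
        with pytest.raises(BlowUpError):
            integrate(spec, grid, record_stride=0)

    def test_zero_coupling_network_preserves_neuron_streams(self):
        # a neuron embedded in a zero-coupling motif sees exactly the noise
        # (hence spikes) of the corresponding isolated run
        grid = SimGrid(dt=0.008, t_total=5000.0, n_realizations=1, seed=9)
        spec3 = NetworkSpec.motif(
            "C2", SynapseSpec("chemical", 0.0, 10.0, "inhibitory"), noise_sigma=0.01
        )
        tr3 = integrate(spec3, grid, record_stride=0)
        for i in range(3):
            tr1 = integrate(
                NetworkSpec.single_neuron(noise_sigma=0.01),
                grid,
                record_stride=0,
                stream_ids=[i],
            )
            assert np.array_equal(tr3.spike_times[i], tr1.spike_times[0])
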