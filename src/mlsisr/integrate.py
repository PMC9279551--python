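"""Stochastic integration of the delayed network equations.

The full system is a set of coupled stochastic delay differential equations
with additive Gaussian white noise entering only the voltage equations:

    dv_i = [f(v_i, w_i) + I_coupling,i(t)] dt + sigma_i dW_i
    dw_i = eps * g(v_i, w_i) dt

Integration uses a two-stage stochastic Runge-Kutta (Heun / SRA family)
step, which for additive noise has strong order 1.0 and weak order 2.0 and
reduces exactly to the deterministic midpoint RK2 scheme at sigma = 0:

    x* = x + a(x) dt + sigma dW
    x' = x + (a(x) + a(x*)) dt / 2 + sigma dW

Delayed voltages are read once per step from a ring buffer at the step's
left endpoint and held constant across the two stages; the initial history
is constant, equal to the initial condition.  Delays are snapped to the
grid when tau/dt is within 1e-9 of an integer and linearly interpolated
otherwise.

Two integration routes are provided:

* :func:`integrate` — the production path, a numba-compiled kernel that
  advances the whole network, detects threshold crossings online (same
  hysteresis rule as :mod:`mlsisr.spikes`) and optionally records a
  (sub-sampled) trajectory;
* :func:`integrate_reference` — a plain-numpy integrator over an arbitrary
  delayed drift callable, used as an independent oracle in tests and for
  small problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np
from numba import njit

from .coupling import (
    KIND_CHEMICAL,
    KIND_ELECTRICAL,
    KIND_ELECTRICAL_AS_PRINTED,
    NetworkSpec,
    compile_edges,
)
from .params import V_SANITY, W_SANITY

__all__ = [
    "SimGrid",
    "HistoryBuffer",
    "Trajectory",
    "delayed_value",
    "integrate",
    "integrate_reference",
    "BlowUpError",
    "V_TH",
    "V_RESET",
]

# Spike threshold (upward crossing) and hysteresis re-arm level shared with
# the spike-statistics module.
V_TH = 0.0
V_RESET = -0.3


class BlowUpError(RuntimeError):
    """A state left the sanity band or became non-finite during integration."""


@dataclass(frozen=True)
class SimGrid:
    """Integration grid and realization plan.

    ``dt`` is the reference step size of the study; ``t_total`` defaults to
    the scaled-down horizon used for desk-scale runs (the reference study
    horizon is 3e5 with 6 realizations).
    """

    dt: float = 0.008
    t_total: float = 3.0e4
    t_transient: Optional[float] = None  # None -> first 10% of t_total
    n_realizations: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if self.transient >= self.t_total:
            raise ValueError("t_transient must be < t_total")

    @property
    def transient(self) -> float:
        return 0.1 * self.t_total if self.t_transient is None else self.t_transient

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total / self.dt))


class HistoryBuffer:
    """Ring of past voltage samples per neuron with constant pre-start history.

    Lookup at lag 0 returns the current value exactly; lags that are exact
    grid multiples return stored samples; other lags are linearly
    interpolated.  Construction fixes the depth against the largest delay in
    the network, and lookups beyond it raise.
    """

    def __init__(self, n_neurons: int, depth: int, dt: float, initial_v: np.ndarray):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.n = n_neurons
        self.depth = depth
        self.dt = dt
        self._init = np.asarray(initial_v, dtype=float).copy()
        self._ring = np.tile(self._init, (depth, 1))
        self._step = 0  # index of the slot holding the *current* value

    @classmethod
    def for_spec(cls, spec: NetworkSpec, dt: float, initial_v: np.ndarray) -> "HistoryBuffer":
        _, _, _, _, delay = compile_edges(spec)
        max_lag = 0 if len(delay) == 0 else int(math.ceil(max(delay) / dt + 1e-9))
        return cls(spec.n_neurons, max_lag + 2, dt, initial_v)

    def push(self, v: np.ndarray) -> None:
        self._step += 1
        self._ring[self._step % self.depth, :] = v

    def value_at_steps_back(self, m: int, i: int) -> float:
        if m > self._step:
            return float(self._init[i])
        return float(self._ring[(self._step - m) % self.depth, i])

    def lookup(self, i: int, lag: float) -> float:
        if lag < 0:
            raise ValueError("lag must be >= 0")
        steps = lag / self.dt
        if steps > self.depth - 1 + 1e-9:
            raise ValueError(f"lag {lag} exceeds buffer depth {self.depth}")
        lo = int(math.floor(steps + 1e-9))
        frac = steps - lo
        if frac < 1e-9:
            return self.value_at_steps_back(lo, i)
        return (1.0 - frac) * self.value_at_steps_back(lo, i) + frac * self.value_at_steps_back(
            lo + 1, i
        )


def delayed_value(buf: HistoryBuffer, lag: float, neuron: int = 0) -> float:
    """Voltage of ``neuron`` a time ``lag`` in the past (see HistoryBuffer)."""
    return buf.lookup(neuron, lag)


@dataclass
class Trajectory:
    """A simulated path: recorded (sub-sampled) time grid and per-neuron
    (v, w) paths, plus online-detected spike times per neuron."""

    t: np.ndarray  # (n_rec,)
    v: np.ndarray  # (n_rec, n)
    w: np.ndarray  # (n_rec, n)
    spike_times: List[np.ndarray]  # per neuron, absolute times
    dt: float
    seed_used: tuple
    realization: int = 0

    @property
    def n_neurons(self) -> int:
        return self.v.shape[1]


# ---------------------------------------------------------------------------
# Compiled kernel
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=False)
def _simulate_kernel(
    v,
    w,  # (n,) state, modified in place
    gc,
    gk,
    gl,
    vk,
    v1,
    v2,
    v3,
    v4,
    vl,
    eps,  # (n,) per-neuron constants
    esrc,
    edst,
    ekind,
    ew,
    elag_lo,
    elag_frac,  # edges
    lam,
    theta,
    vsyn,  # chemical constants
    sigma,  # (n,)
    dt,
    n_steps,
    use_noise,
    noise,  # (n_steps, n) standard normals, or (1, 1) dummy
    ring,  # (depth, n) prefilled with v
    record_stride,
    traj_v,
    traj_w,  # (n_rec, n) or (1, 1) dummies
    v_th,
    v_reset,
    spike_times,  # (n, max_spikes)
    spike_counts,  # (n,) int64, zeroed
    v_lo,
    v_hi,
    w_lo,
    w_hi,
):
    n = v.shape[0]
    ne = esrc.shape[0]
    depth = ring.shape[0]
    sqrt_dt = math.sqrt(dt)

    armed = np.empty(n, np.bool_)
    for i in range(n):
        armed[i] = v[i] < v_reset
    a1v = np.empty(n)
    a1w = np.empty(n)
    pv = np.empty(n)
    pw = np.empty(n)
    dWs = np.zeros(n)
    # frozen per-edge quantities for the current step
    eq = np.empty(ne)

    status = 0
    for k in range(n_steps):
        # store current voltages at slot k
        for i in range(n):
            ring[k % depth, i] = v[i]

        # freeze delayed quantities at the left endpoint
        for e in range(ne):
            src_i = esrc[e] if ekind[e] != KIND_ELECTRICAL_AS_PRINTED else edst[e]
            lo = elag_lo[e]
            frac = elag_frac[e]
            m = k - lo
            vd_lo = ring[m % depth, src_i] if m >= 0 else _hist0(ring, src_i)
            if frac > 0.0:
                m2 = m - 1
                vd_hi = ring[m2 % depth, src_i] if m2 >= 0 else _hist0(ring, src_i)
                vd = (1.0 - frac) * vd_lo + frac * vd_hi
            else:
                vd = vd_lo
            if ekind[e] == KIND_CHEMICAL:
                eq[e] = 1.0 / (1.0 + math.exp(-lam * (vd - theta)))
            else:
                eq[e] = vd

        if use_noise:
            for i in range(n):
                if sigma[i] > 0.0:
                    dWs[i] = sigma[i] * sqrt_dt * noise[k, i]
                else:
                    dWs[i] = 0.0

        # stage 1
        for i in range(n):
            a1v[i] = _fv(v[i], w[i], gc[i], gk[i], gl[i], vk[i], v1[i], v2[i], vl[i])
            a1w[i] = _gw(v[i], w[i], v3[i], v4[i], eps[i])
        for e in range(ne):
            d = edst[e]
            if ekind[e] == KIND_ELECTRICAL:
                a1v[d] += ew[e] * (eq[e] - v[d])
            elif ekind[e] == KIND_ELECTRICAL_AS_PRINTED:
                a1v[d] += ew[e] * (eq[e] - v[esrc[e]])
            else:
                a1v[d] += ew[e] * (v[d] - vsyn) * eq[e]
        for i in range(n):
            pv[i] = v[i] + a1v[i] * dt + dWs[i]
            pw[i] = w[i] + a1w[i] * dt

        # stage 2 (delayed quantities held)
        for i in range(n):
            a2v = _fv(pv[i], pw[i], gc[i], gk[i], gl[i], vk[i], v1[i], v2[i], vl[i])
            a2w = _gw(pv[i], pw[i], v3[i], v4[i], eps[i])
            a1v[i] = 0.5 * (a1v[i] + a2v)
            a1w[i] = 0.5 * (a1w[i] + a2w)
        for e in range(ne):
            d = edst[e]
            if ekind[e] == KIND_ELECTRICAL:
                a1v[d] += 0.5 * ew[e] * (eq[e] - pv[d])
            elif ekind[e] == KIND_ELECTRICAL_AS_PRINTED:
                a1v[d] += 0.5 * ew[e] * (eq[e] - pv[esrc[e]])
            else:
                a1v[d] += 0.5 * ew[e] * (pv[d] - vsyn) * eq[e]

        t_new = (k + 1) * dt
        for i in range(n):
            v_new = v[i] + a1v[i] * dt + dWs[i]
            w_new = w[i] + a1w[i] * dt
            if not (v_lo < v_new < v_hi) or not (w_lo < w_new < w_hi) or v_new != v_new:
                return 1
            # online spike detection with hysteresis
            if armed[i] and v[i] <= v_th < v_new:
                c = spike_counts[i]
                if c >= spike_times.shape[1]:
                    return 2
                frac_t = (v_th - v[i]) / (v_new - v[i])
                spike_times[i, c] = t_new - dt + frac_t * dt
                spike_counts[i] = c + 1
                armed[i] = False
            if v_new < v_reset:
                armed[i] = True
            v[i] = v_new
            w[i] = w_new

        if record_stride > 0 and (k + 1) % record_stride == 0:
            r = (k + 1) // record_stride - 1
            if r < traj_v.shape[0]:
                for i in range(n):
                    traj_v[r, i] = v[i]
                    traj_w[r, i] = w[i]
    return status


@njit(cache=True, inline="always")
def _hist0(ring, i):
    # slot 0 is never overwritten before step >= depth; by then m >= 0 for
    # all admissible lags, so slot 0 still holds the constant initial value
    # whenever this is called.
    return ring[0, i]


@njit(cache=True, inline="always")
def _fv(v, w, gc, gk, gl, vk, v1, v2, vl):
    m = 0.5 * (1.0 + math.tanh((v - v1) / v2))
    return gc * m * (1.0 - v) + gl * (vl - v) + gk * w * (vk - v)


@njit(cache=True, inline="always")
def _gw(v, w, v3, v4, eps):
    x = (v - v3) / v4
    return eps * math.cosh(x) * (0.5 * (1.0 + math.tanh(x)) - w)


def _param_arrays(spec: NetworkSpec):
    ps = [lay.params for lay in spec.layers for _ in range(spec.neurons_per_layer)]
    names = ["g_c", "g_k", "g_l", "v_k", "v_1", "v_2", "v_3", "v_4", "v_l", "epsilon"]
    return [np.array([getattr(p, nm) for p in ps], dtype=float) for nm in names]


def _edge_arrays(spec: NetworkSpec, dt: float):
    src, dst, kind, weight, delay = compile_edges(spec)
    steps = delay / dt
    lo = np.floor(steps + 1e-9).astype(np.int64)
    frac = steps - lo
    frac[frac < 1e-9] = 0.0
    return src, dst, kind, weight, lo, frac


def _noise_array(
    base_seed: int, realization: int, stream_ids: Sequence[int], n_steps: int
) -> np.ndarray:
    """(n_steps, n) standard normals; column i comes from the independent
    counter-based (Philox) stream keyed by (base_seed, realization,
    stream_ids[i]), so a neuron keeps its noise path when embedded in a
    larger network."""
    out = np.empty((n_steps, len(stream_ids)))
    for col, sid in enumerate(stream_ids):
        rng = np.random.Generator(
            np.random.Philox(key=np.random.SeedSequence(
                entropy=int(base_seed), spawn_key=(int(realization), int(sid))
            ).generate_state(2, dtype=np.uint64))
        )
        out[:, col] = rng.standard_normal(n_steps)
    return out


def integrate(
    spec: NetworkSpec,
    grid: SimGrid,
    initial: Optional[np.ndarray] = None,
    realization: int = 0,
    record_stride: Optional[int] = None,
    max_spikes: Optional[int] = None,
    check_blowup: bool = True,
    stream_ids: Optional[Sequence[int]] = None,
) -> Trajectory:
    """Advance the network over ``grid`` for one realization.

    ``initial`` is an (n, 2) array of (v, w) rows; by default the isolated
    fixed point of each layer's neuron parameters (computed upstream callers
    normally pass the coupled fixed point).  Returns a :class:`Trajectory`
    with the recorded path (every ``record_stride`` steps; None records
    roughly 4000 samples, 0 disables recording) and per-neuron spike times
    detected online (threshold V_TH, hysteresis V_RESET).
    """
    n = spec.n_neurons
    if initial is None:
        from .analysis import find_fixed_point

        fps = []
        for lay in spec.layers:
            fp = find_fixed_point(lay.params)
            fps.extend([[fp.v_e, fp.w_e]] * spec.neurons_per_layer)
        initial = np.asarray(fps, dtype=float)
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (n, 2):
        raise ValueError(f"initial must have shape ({n}, 2)")

    n_steps = grid.n_steps
    if record_stride is None:
        record_stride = max(1, n_steps // 4000)
    n_rec = n_steps // record_stride if record_stride > 0 else 0

    (gc, gk, gl, vk, v1, v2, v3, v4, vl, eps) = _param_arrays(spec)
    src, dst, kind, weight, lag_lo, lag_frac = _edge_arrays(spec, grid.dt)
    max_lo = int(lag_lo.max() + 1) if len(lag_lo) else 0
    depth = max_lo + 2
    if depth > n_steps + 2:
        depth = n_steps + 2

    v = initial[:, 0].copy()
    w = initial[:, 1].copy()
    ring = np.tile(v, (depth, 1))
    sigma = spec.sigmas.astype(float)
    use_noise = bool((sigma > 0).any())
    if stream_ids is None:
        stream_ids = list(range(n))
    noise = (
        _noise_array(grid.seed, realization, stream_ids, n_steps)
        if use_noise
        else np.zeros((1, 1))
    )

    traj_v = np.empty((n_rec, n)) if n_rec else np.empty((1, 1))
    traj_w = np.empty((n_rec, n)) if n_rec else np.empty((1, 1))
    if max_spikes is None:
        # relaxation-oscillation periods are O(100) time units or more
        max_spikes = max(1024, int(grid.t_total / 25.0))
    spike_times = np.empty((n, max_spikes))
    spike_counts = np.zeros(n, dtype=np.int64)

    c = spec.chemical
    v_lo, v_hi = V_SANITY if check_blowup else (-1e12, 1e12)
    w_lo, w_hi = W_SANITY if check_blowup else (-1e12, 1e12)

    status = _simulate_kernel(
        v, w, gc, gk, gl, vk, v1, v2, v3, v4, vl, eps,
        src, dst, kind, weight, lag_lo, lag_frac,
        c.lambda_slope, c.theta_syn, c.v_syn,
        sigma, grid.dt, n_steps, use_noise, noise, ring,
        record_stride if n_rec else 0, traj_v, traj_w,
        V_TH, V_RESET, spike_times, spike_counts,
        v_lo, v_hi, w_lo, w_hi,
    )
    if status == 1:
        raise BlowUpError(
            "state left the sanity band (v in %s, w in %s): integration diverged"
            % (V_SANITY, W_SANITY)
        )
    if status == 2:
        raise RuntimeError("spike buffer overflow; raise max_spikes")

    t = (np.arange(1, n_rec + 1) * record_stride * grid.dt) if n_rec else np.empty(0)
    spikes = [spike_times[i, : spike_counts[i]].copy() for i in range(n)]
    return Trajectory(
        t=t,
        v=traj_v if n_rec else np.empty((0, n)),
        w=traj_w if n_rec else np.empty((0, n)),
        spike_times=spikes,
        dt=grid.dt,
        seed_used=(grid.seed, realization, tuple(stream_ids)),
        realization=realization,
    )


# ---------------------------------------------------------------------------
# Reference integrator (independent oracle path)
# ---------------------------------------------------------------------------


def integrate_reference(
    drift: Callable[[np.ndarray, Callable[[int, float], float], float], np.ndarray],
    initial: np.ndarray,
    dt: float,
    n_steps: int,
    sigma: Optional[np.ndarray] = None,
    noise: Optional[np.ndarray] = None,
    max_lag: float = 0.0,
):
    """Plain-numpy Heun integration of an arbitrary delayed drift.

    ``drift(states, history, t)`` maps the (n, 2) state and a voltage
    history accessor to (n, 2) rates.  ``noise`` is an optional
    (n_steps, n) array of standard normals scaled internally by
    sigma*sqrt(dt) and added to the v channel; delayed voltages are frozen
    at the step's left endpoint exactly as in the compiled kernel (the
    history accessor returns left-endpoint values during both stages).
    Returns (t, states_path) with states_path of shape (n_steps+1, n, 2).
    """
    states = np.asarray(initial, dtype=float).copy()
    n = states.shape[0]
    depth = int(math.ceil(max_lag / dt + 1e-9)) + 2
    buf = HistoryBuffer(n, depth, dt, states[:, 0])
    path = np.empty((n_steps + 1, n, 2))
    path[0] = states
    sqrt_dt = math.sqrt(dt)
    sig = np.zeros(n) if sigma is None else np.asarray(sigma, dtype=float)

    for k in range(n_steps):
        t = k * dt
        hist = buf.lookup  # frozen at left endpoint for both stages
        dW = np.zeros(n)
        if noise is not None:
            dW = sig * sqrt_dt * noise[k]
        a1 = drift(states, hist, t)
        pred = states + a1 * dt
        pred[:, 0] += dW
        a2 = drift(pred, hist, t + dt)
        states = states + 0.5 * (a1 + a2) * dt
        states[:, 0] += dW
        buf.push(states[:, 0])
        path[k + 1] = states
    t_grid = np.arange(n_steps + 1) * dt
    return t_grid, path
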