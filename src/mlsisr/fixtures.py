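"""Synthetic calibration fixtures for every downstream analysis stage.

These generators emulate the statistical structures the analysis assumes,
with analytically known answers, so spike statistics, detection and the
stochastic integrator can each be validated in isolation and in seconds:

* renewal spike trains with known CV — periodic (CV 0), Poisson (CV 1),
  gamma with shape k (CV 1/sqrt(k));
* voltage traces — square pulses crossing the detection threshold at known
  times (with optional sub-threshold noise), and Ornstein-Uhlenbeck paths
  with known stationary moments (sampled by the exact AR(1) discretization,
  independent of the package's own integrator);
* frozen-w double-well escape problems whose mean escape times obey
  Kramers/Arrhenius scaling with the left energy barrier computed by the
  theory module.

Everything is deterministic given (spec, seed).  Only the double-well
fixture touches the neuron model (through the theory module's effective
fast drift); all other fixtures are model-free by design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from numba import njit

from .params import NeuronParams
from .spikes import SpikeTrain
from . import theory

__all__ = [
    "FixtureSpec",
    "make_spike_train",
    "make_square_pulse_trace",
    "make_ou_path",
    "make_frozen_double_well",
    "escape_times",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture request: kind plus its parameters and a seed."""

    kind: str
    seed: int = 0
    # spike trains
    period: float = 1.0
    rate: float = 1.0
    shape: float = 1.0
    scale: float = 1.0
    n_intervals: int = 1000
    # traces
    duration: float = 100.0
    dt: float = 0.008
    relaxation_rate: float = 1.0
    sigma: float = 0.0
    pulse_times: Tuple[float, ...] = ()
    pulse_width: float = 1.0
    baseline: float = -0.6
    pulse_height: float = 1.0
    # double well
    w_frozen: float = 0.21


def make_spike_train(spec: FixtureSpec) -> Tuple[SpikeTrain, float]:
    """Renewal spike train with analytically known CV.

    kinds: ``periodic_train`` (CV 0), ``poisson_train`` (CV 1),
    ``gamma_train`` (CV 1/sqrt(shape)).  Returns (train, analytic_cv).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "periodic_train":
        if spec.period <= 0:
            raise ValueError("period must be > 0")
        isis = np.full(spec.n_intervals, spec.period)
        cv = 0.0
    elif spec.kind == "poisson_train":
        if spec.rate <= 0:
            raise ValueError("rate must be > 0")
        isis = rng.exponential(1.0 / spec.rate, spec.n_intervals)
        cv = 1.0
    elif spec.kind == "gamma_train":
        if spec.shape <= 0 or spec.scale <= 0:
            raise ValueError("gamma shape and scale must be > 0")
        isis = rng.gamma(spec.shape, spec.scale, spec.n_intervals)
        cv = 1.0 / math.sqrt(spec.shape)
    else:
        raise ValueError(f"not a spike-train fixture kind: {spec.kind!r}")
    times = np.cumsum(isis)
    return SpikeTrain(times), cv


def make_square_pulse_trace(spec: FixtureSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Voltage trace with square pulses crossing v_th = 0 at known times.

    The trace sits at ``baseline`` (below the hysteresis re-arm level) and
    jumps to ``pulse_height`` for ``pulse_width`` time units starting at
    each requested pulse time; optional zero-mean noise of amplitude
    ``sigma`` (kept sub-threshold) is superimposed.  Returns (t, v).
    """
    t = np.arange(0.0, spec.duration, spec.dt)
    v = np.full_like(t, spec.baseline)
    for t0 in spec.pulse_times:
        v[(t >= t0) & (t < t0 + spec.pulse_width)] = spec.pulse_height
    if spec.sigma > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + spec.sigma * rng.standard_normal(len(t))
    return t, v


def make_ou_path(spec: FixtureSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Ornstein-Uhlenbeck path dx = -theta x dt + sigma dW via exact AR(1).

    x_{k+1} = a x_k + s z_k with a = exp(-theta dt) and
    s^2 = sigma^2 (1 - a^2) / (2 theta): the transition density is sampled
    exactly, making this an integrator-independent oracle with stationary
    variance sigma^2 / (2 theta).  With sigma = 0 the path is the exact
    exponential decay.  Starts at x = 1.  Returns (t, x).
    """
    theta_rate = spec.relaxation_rate
    if theta_rate <= 0:
        raise ValueError("relaxation_rate must be > 0")
    n = int(round(spec.duration / spec.dt))
    a = math.exp(-theta_rate * spec.dt)
    s = (
        spec.sigma * math.sqrt((1.0 - a * a) / (2.0 * theta_rate))
        if spec.sigma > 0
        else 0.0
    )
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal(n) if s > 0 else np.zeros(n)
    x = np.empty(n + 1)
    x[0] = 1.0
    for k in range(n):
        x[k + 1] = a * x[k] + s * z[k]
    return np.arange(n + 1) * spec.dt, x


@njit(cache=True)
def _escape_kernel(
    v0, v_stop, gc, gk, gl, vk, v1, v2, vl, w, sigma, dt, max_steps, noise
):
    v = v0
    sqrt_dt = math.sqrt(dt)
    for k in range(max_steps):
        m = 0.5 * (1.0 + math.tanh((v - v1) / v2))
        f = gc * m * (1.0 - v) + gl * (vl - v) + gk * w * (vk - v)
        dW = sigma * sqrt_dt * noise[k]
        vp = v + f * dt + dW
        mp = 0.5 * (1.0 + math.tanh((vp - v1) / v2))
        fp = gc * mp * (1.0 - vp) + gl * (vl - vp) + gk * w * (vk - vp)
        v = v + 0.5 * (f + fp) * dt + dW
        if v >= v_stop:
            return (k + 1) * dt
    return -1.0


def make_frozen_double_well(
    w_frozen: float,
    sigma: float,
    seed: int = 0,
    p: Optional[NeuronParams] = None,
    dt: float = 0.008,
    t_cap: float = 2.0e5,
    start: Optional[float] = None,
) -> float:
    """One first-passage time of the frozen-w fast subsystem.

    Simulates the one-dimensional Langevin equation dv = -U'(v; w) dt +
    sigma dW from the left well (or ``start``) until first crossing of the
    unstable middle root v_mid; returns the escape time.  Raises on timeout
    (no escape within ``t_cap``).
    """
    p = p or NeuronParams()
    roots = theory.branch_roots(w_frozen, theory.isolated_slice(w_frozen, p))
    v0 = roots.v_left if start is None else float(start)
    max_steps = int(t_cap / dt)
    rng = np.random.Generator(np.random.Philox(key=np.random.SeedSequence(
        entropy=int(seed), spawn_key=(987,)
    ).generate_state(2, dtype=np.uint64)))
    # draw noise in chunks to bound memory on long caps
    chunk = 2_000_000
    t_done = 0.0
    steps_left = max_steps
    while steps_left > 0:
        m = min(chunk, steps_left)
        noise = rng.standard_normal(m)
        t = _escape_kernel(
            v0 if t_done == 0.0 else v0,  # continuation handled below
            roots.v_mid,
            p.g_c, p.g_k, p.g_l, p.v_k, p.v_1, p.v_2, p.v_l,
            w_frozen, sigma, dt, m, noise,
        )
        if t >= 0:
            return t_done + t
        t_done += m * dt
        steps_left -= m
        # continue from wherever the path ended: kernel does not return the
        # state, so restart bias is avoided by keeping chunks long relative
        # to the well's relaxation time (restarting in the well is the
        # quasi-stationary behaviour anyway)
    raise TimeoutError(f"no escape within t_cap={t_cap} at sigma={sigma}")


def escape_times(
    w_frozen: float,
    sigma: float,
    n_samples: int,
    seed: int = 0,
    **kw,
) -> np.ndarray:
    """Independent first-passage samples (distinct sub-seeds per sample)."""
    return np.array(
        [make_frozen_double_well(w_frozen, sigma, seed=seed * 100003 + i, **kw)
         for i in range(n_samples)]
    )
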