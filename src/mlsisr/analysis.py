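"""Zero-noise analysis: fixed points, Hopf bifurcation, excitability maps.

Self-induced stochastic resonance requires the deterministic system to be
excitable: a unique stable fixed point and no limit cycle, so that all
oscillations observed under noise are genuinely noise-induced.  This module
provides that guarantee: the isolated neuron's fixed point and its
timescale-dependent Hopf bifurcation value (via the analytic Jacobian), a
steady state for coupled delayed networks, and simulation-based
excitable/oscillatory classification over coupling-parameter planes (the
delayed systems are classified by direct simulation, not by
characteristic-equation analysis, since delay-induced onsets may be
saddle-node-onto-limit-cycle rather than Hopf).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .coupling import NetworkSpec, assemble_drift
from .integrate import SimGrid, integrate
from .params import (
    NeuronParams,
    StatePoint,
    activation_w,
    ml_drift,
    ml_jacobian,
    v_nullcline_w,
)

__all__ = [
    "FixedPoint",
    "HopfResult",
    "ExcitabilityResult",
    "ExcitabilityMap",
    "find_fixed_point",
    "hopf_value",
    "oscillation_onset",
    "network_fixed_point",
    "classify_excitability",
    "excitability_map",
]

_V_SCAN = (-1.4, 2.5)

# Excitability-test protocol: deterministic horizon, suprathreshold kick on
# every neuron, and the fraction of the run discarded as transient.
EXC_HORIZON = 5000.0
EXC_KICK = 0.3
EXC_TRANSIENT_FRAC = 0.2


@dataclass(frozen=True)
class FixedPoint:
    v_e: float
    w_e: float
    stability: str  # "stable" | "unstable"
    eigen_real_max: float


@dataclass(frozen=True)
class HopfResult:
    epsilon: float
    v_hopf: float
    bracket: Tuple[float, float]


def _nullcline_gap(v: float, p: NeuronParams) -> float:
    return float(v_nullcline_w(v, p) - activation_w(v, p))


def find_fixed_point(p: NeuronParams, scan_points: int = 2000) -> FixedPoint:
    """Unique intersection of the v- and w-nullclines, with stability.

    Brackets sign changes of w_null(v) - w_inf(v) on a dense voltage scan,
    refines by Brent's method, and classifies stability from the analytic
    Jacobian of (f, eps*g).  Raises if the scan finds other than exactly one
    intersection.
    """
    vs = np.linspace(*_V_SCAN, scan_points)
    gap = v_nullcline_w(vs, p) - activation_w(vs, p)
    sign_changes = np.nonzero(np.diff(np.sign(gap)) != 0)[0]
    if len(sign_changes) != 1:
        raise ValueError(
            f"expected a unique nullcline intersection, found {len(sign_changes)}"
        )
    i = sign_changes[0]
    v_e = optimize.brentq(_nullcline_gap, vs[i], vs[i + 1], args=(p,), xtol=1e-14)
    w_e = float(activation_w(v_e, p))
    # polish with a damped Newton on the 2-D drift
    sol = optimize.root(
        lambda x: ml_drift(StatePoint(x[0], x[1]), p), [v_e, w_e], method="hybr", tol=1e-14
    )
    if sol.success:
        v_e, w_e = float(sol.x[0]), float(sol.x[1])
    eig = np.linalg.eigvals(ml_jacobian(StatePoint(v_e, w_e), p))
    lam_max = float(eig.real.max())
    return FixedPoint(v_e, w_e, "stable" if lam_max < 0 else "unstable", lam_max)


def _eigen_real_max(v_l: float, p: NeuronParams) -> float:
    fp = find_fixed_point(p.with_(v_l=v_l))
    return fp.eigen_real_max


def hopf_value(
    epsilon: float,
    base: Optional[NeuronParams] = None,
    bracket: Tuple[float, float] = (1.50, 1.60),
    tol: float = 1e-6,
) -> HopfResult:
    """Hopf bifurcation value of v_l at a given timescale separation.

    Bisects the sign change of the largest eigenvalue real part of the
    analytic Jacobian at the fixed point over ``bracket``; raises if there
    is no sign change.
    """
    if not (1e-6 <= epsilon <= 1e-2):
        raise ValueError("epsilon outside supported range [1e-6, 1e-2]")
    p = (base or NeuronParams()).with_(epsilon=epsilon)
    lo, hi = bracket
    f_lo, f_hi = _eigen_real_max(lo, p), _eigen_real_max(hi, p)
    if f_lo * f_hi > 0:
        raise ValueError(f"no stability change of the fixed point in {bracket}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _eigen_real_max(mid, p) * f_lo <= 0:
            hi = mid
        else:
            lo = mid
    return HopfResult(epsilon=epsilon, v_hopf=0.5 * (lo + hi), bracket=(lo, hi))


def oscillation_onset(
    epsilon: float,
    base: Optional[NeuronParams] = None,
    bracket: Tuple[float, float] = (1.50, 1.60),
    tol: float = 1e-4,
    horizon: float = 2.0e4,
    dt: float = 0.008,
) -> HopfResult:
    """Onset of sustained oscillation in v_l, located by simulation bisection.

    In this slow-fast neuron the linearized (eigenvalue) Hopf point and the
    value at which a kicked trajectory first settles onto the large
    relaxation limit cycle differ at order eps (canard regime): the large
    cycle becomes attracting slightly below the eigenvalue crossing's
    location at finite kick amplitudes.  This routine bisects the
    excitable/oscillatory boundary observed in direct integration (same
    protocol as :func:`classify_excitability`), which is the operationally
    relevant oscillation threshold for excitability checks.
    """
    p = (base or NeuronParams()).with_(epsilon=epsilon)

    def oscillatory(v_l: float) -> bool:
        spec = NetworkSpec.single_neuron(params=p.with_(v_l=v_l))
        res = classify_excitability(spec, horizon=horizon, dt=dt)
        return res.classification == "oscillatory"

    lo, hi = bracket
    if oscillatory(lo) or not oscillatory(hi):
        raise ValueError(f"onset not bracketed by {bracket}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if oscillatory(mid):
            hi = mid
        else:
            lo = mid
    return HopfResult(epsilon=epsilon, v_hopf=0.5 * (lo + hi), bracket=(lo, hi))


def network_fixed_point(spec: NetworkSpec) -> np.ndarray:
    """Steady state of the deterministic delayed network, shape (n, 2).

    At a steady state delayed values equal present values, so the fixed
    point solves the undelayed algebraic system; it is sought by a damped
    root find seeded from the isolated-neuron fixed point of each layer.
    Falls back to the isolated seed if the solver fails (e.g. when no
    steady state exists near the excitable branch).
    """
    drift = assemble_drift(spec)
    n = spec.n_neurons
    seed_rows = []
    for lay in spec.layers:
        fp = find_fixed_point(lay.params)
        seed_rows.extend([[fp.v_e, fp.w_e]] * spec.neurons_per_layer)
    x0 = np.asarray(seed_rows, dtype=float)

    def fun(x_flat: np.ndarray) -> np.ndarray:
        states = x_flat.reshape(n, 2)
        v_now = states[:, 0]
        hist = lambda i, lag: float(v_now[i])  # steady state: v(t-lag) = v(t)
        return drift(states, hist, 0.0).ravel()

    sol = optimize.root(fun, x0.ravel(), method="hybr", tol=1e-13)
    if sol.success and np.max(np.abs(fun(sol.x))) < 1e-9:
        return sol.x.reshape(n, 2)
    return x0


@dataclass(frozen=True)
class ExcitabilityResult:
    classification: str  # "excitable" | "oscillatory"
    mean_isi: Optional[float]  # network-mean ISI, oscillatory cells only
    n_spikes_post_transient: int


def classify_excitability(
    spec: NetworkSpec,
    horizon: float = EXC_HORIZON,
    dt: float = 0.008,
) -> ExcitabilityResult:
    """Excitable vs oscillatory classification of the zero-noise network.

    Protocol: start at the network steady state with a suprathreshold kick
    (+0.3 on every voltage), integrate deterministically for ``horizon``
    time units, discard the first 20%, and classify as oscillatory iff
    sustained spiking (>= 2 spikes on some neuron) persists past the
    transient.  The kick distinguishes a single excitable excursion from a
    limit cycle reached via delay-induced bifurcations.
    """
    if (spec.sigmas > 0).any():
        spec = spec.with_sigma(0.0)
    x0 = network_fixed_point(spec)
    x0 = x0.copy()
    x0[:, 0] += EXC_KICK
    grid = SimGrid(dt=dt, t_total=horizon, t_transient=EXC_TRANSIENT_FRAC * horizon,
                   n_realizations=1, seed=0)
    traj = integrate(spec, grid, initial=x0, record_stride=0)
    t_cut = grid.transient
    post = [st[st >= t_cut] for st in traj.spike_times]
    n_post = int(sum(len(s) for s in post))
    isis = [np.diff(s) for s in post if len(s) >= 2]
    if isis:
        mean_isi = float(np.mean([x.mean() for x in isis]))
        return ExcitabilityResult("oscillatory", mean_isi, n_post)
    return ExcitabilityResult("excitable", None, n_post)


@dataclass
class ExcitabilityMap:
    """Per-cell classification over a (coupling strength, delay) plane."""

    kappa_grid: np.ndarray
    tau_grid: np.ndarray
    classification: np.ndarray  # (n_kappa, n_tau) of {"excitable","oscillatory","failed"}
    mean_isi: np.ndarray  # NaN where excitable/failed

    def fraction(self, cls: str) -> float:
        return float((self.classification == cls).mean())

    def to_records(self) -> List[dict]:
        out = []
        for a, k in enumerate(self.kappa_grid):
            for b, t in enumerate(self.tau_grid):
                out.append(
                    dict(
                        kappa=float(k),
                        tau=float(t),
                        classification=str(self.classification[a, b]),
                        mean_isi=float(self.mean_isi[a, b]),
                    )
                )
        return out


def excitability_map(
    spec_factory: Callable[[float, float], NetworkSpec],
    kappa_grid: Sequence = (0.0, 0.375, 0.75, 1.125, 1.5),
    tau_grid: Sequence = (0.0, 5.0, 10.0, 15.0, 20.0),
    horizon: float = EXC_HORIZON,
    dt: float = 0.008,
) -> ExcitabilityMap:
    """Classify every (kappa, tau) cell of a coupling plane.

    ``spec_factory(kappa, tau)`` builds the zero-noise network for one cell.
    Per-cell failures (blow-up, no steady state) are recorded as a distinct
    "failed" class; the map always completes.
    """
    kappa_grid = np.asarray(list(kappa_grid), dtype=float)
    tau_grid = np.asarray(list(tau_grid), dtype=float)
    cls = np.empty((len(kappa_grid), len(tau_grid)), dtype=object)
    isi = np.full((len(kappa_grid), len(tau_grid)), np.nan)
    for a, k in enumerate(kappa_grid):
        for b, t in enumerate(tau_grid):
            try:
                res = classify_excitability(spec_factory(float(k), float(t)),
                                            horizon=horizon, dt=dt)
                cls[a, b] = res.classification
                if res.mean_isi is not None:
                    isi[a, b] = res.mean_isi
            except Exception:
                cls[a, b] = "failed"
    return ExcitabilityMap(kappa_grid, tau_grid, cls, isi)
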