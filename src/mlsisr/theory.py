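"""Large-deviation predictions for SISR: frozen-w double well and noise window.

In the adiabatic limit eps -> 0 the slow recovery variable w is frozen and
each voltage equation reduces to a Langevin equation in a one-dimensional
potential U(v; w) with dU/dv = -(effective drift).  For w inside the
bistable range the fast drift has three zeros

    v_left < v_mid < v_right

(the left stable, middle unstable and right stable branches of the S-shaped
v-nullcline), and escape over either barrier

    dU_left(w)  = U(v_mid) - U(v_left)
    dU_right(w) = U(v_mid) - U(v_right)

follows Kramers' law.  SISR occurs for noise amplitudes sigma with
sigma^2/2 * ln(1/eps) inside [dU_left(w_e), F], where w_e is the recovery
value of the stable fixed point and F is the common barrier height at the
recovery value w* where the two barriers are equal; equivalently

    sigma_min = sqrt(2 dU_left(w_e) / ln(1/eps)),
    sigma_max = sqrt(2 F / ln(1/eps)).

For coupled networks the same construction applies per neuron with all
coupling inputs frozen at their fixed-point (steady-state) values, so the
chemical gate and the delayed electrical source voltage become constants of
the slice; setting every coupling strength to zero recovers the
isolated-neuron quantities exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy import integrate as sp_integrate
from scipy import optimize

from .coupling import KIND_CHEMICAL, NetworkSpec, compile_edges
from .params import NeuronParams

__all__ = [
    "PotentialSlice",
    "BranchRoots",
    "BarrierProfile",
    "SigmaBounds",
    "isolated_slice",
    "coupled_slice",
    "branch_roots",
    "barrier",
    "barrier_profile",
    "sigma_bounds",
    "bistable_w_range",
]

_V_SCAN = (-1.4, 2.5)
# Fine bracketing grid: near the fixed point the left well is extremely
# shallow (barrier ~1e-6), so the left root pair can be ~1e-2 apart.
_ROOT_GRID = 40001


@dataclass(frozen=True)
class PotentialSlice:
    """Frozen-w (and frozen-inputs) one-dimensional fast subsystem.

    ``drift(v)`` is the effective voltage drift at the frozen recovery value
    ``w_frozen`` with all coupling inputs held at ``frozen_inputs`` (a
    description recorded for provenance); ``potential(v)`` integrates
    -drift from a fixed reference so barrier differences are
    constant-free.
    """

    w_frozen: float
    drift: Callable[[float], float]
    frozen_inputs: tuple = ()

    def potential(self, v: float, v_ref: float = 0.0) -> float:
        val, _ = sp_integrate.quad(lambda x: -self.drift(x), v_ref, v, limit=200)
        return val


def _fast_drift_fn(p: NeuronParams, w: float, terms: Sequence[Tuple[float, float]] = ()):
    """Vectorized effective fast drift v -> f(v, w) + sum(alpha + beta*v)."""
    alpha = sum(a for a, _ in terms)
    beta = sum(b for _, b in terms)

    def drift(v):
        v = np.asarray(v, dtype=float)
        m = 0.5 * (1.0 + np.tanh((v - p.v_1) / p.v_2))
        out = (
            p.g_c * m * (1.0 - v)
            + p.g_l * (p.v_l - v)
            + p.g_k * w * (p.v_k - v)
            + alpha
            + beta * v
        )
        return out if out.ndim else float(out)

    return drift


def isolated_slice(w: float, p: Optional[NeuronParams] = None) -> PotentialSlice:
    """Fast subsystem of an isolated neuron at frozen recovery value w."""
    p = p or NeuronParams()
    return PotentialSlice(w_frozen=w, drift=_fast_drift_fn(p, w))


def coupled_slice(
    spec: NetworkSpec,
    neuron: int,
    w: float,
    frozen_v: Optional[np.ndarray] = None,
) -> PotentialSlice:
    """Fast subsystem of neuron ``neuron`` in a coupled network.

    All other (delayed) voltages are frozen at ``frozen_v`` (default: the
    deterministic network steady state), making every coupling term affine
    in the neuron's own voltage.  With all coupling strengths zero this
    reduces exactly to :func:`isolated_slice`.
    """
    if spec.electrical_convention != "conventional":
        raise ValueError("potential slices are defined for the conventional electrical form")
    if frozen_v is None:
        from .analysis import network_fixed_point

        frozen_v = network_fixed_point(spec)[:, 0]
    frozen_v = np.asarray(frozen_v, dtype=float)
    params = [lay.params for lay in spec.layers for _ in range(spec.neurons_per_layer)]
    p = params[neuron]
    src, dst, kind, weight, _delay = compile_edges(spec)
    c = spec.chemical
    terms = []  # (alpha, beta): current = alpha + beta * v
    for e in range(len(src)):
        if dst[e] != neuron:
            continue
        if kind[e] == KIND_CHEMICAL:
            gate = 1.0 / (1.0 + math.exp(-c.lambda_slope * (frozen_v[src[e]] - c.theta_syn)))
            # +/-kappa * (v - v_syn) * gate
            terms.append((-weight[e] * gate * c.v_syn, weight[e] * gate))
        else:
            # kappa * (v_src_frozen - v); the own delayed voltage of an
            # autapse is likewise frozen at the steady state
            terms.append((weight[e] * frozen_v[src[e]], -weight[e]))

    return PotentialSlice(
        w_frozen=w, drift=_fast_drift_fn(p, w, terms), frozen_inputs=tuple(frozen_v)
    )


@dataclass(frozen=True)
class BranchRoots:
    v_left: float
    v_mid: float
    v_right: float

    def __iter__(self):
        return iter((self.v_left, self.v_mid, self.v_right))


def _all_roots(slice_: PotentialSlice) -> list:
    vs = np.linspace(*_V_SCAN, _ROOT_GRID)
    fs = np.asarray(slice_.drift(vs))
    roots = []
    idx = np.nonzero(np.sign(fs[:-1]) * np.sign(fs[1:]) < 0)[0]
    for i in idx:
        r = optimize.brentq(slice_.drift, vs[i], vs[i + 1], xtol=1e-12, rtol=8.9e-16)
        roots.append(float(r))
    # exact grid zeros (rare)
    for i in np.nonzero(fs == 0.0)[0]:
        roots.append(float(vs[i]))
    return sorted(roots)


def branch_roots(w: float, slice_: Optional[PotentialSlice] = None,
                 p: Optional[NeuronParams] = None) -> BranchRoots:
    """The three zeros of the effective fast drift at frozen w.

    Sign-change bracketing on a dense grid plus Brent refinement; returns
    the ordered triple or raises: one root means w is outside the bistable
    range, two roots a fold point.
    """
    s = slice_ if slice_ is not None else isolated_slice(w, p)
    roots = _all_roots(s)
    if len(roots) == 3:
        return BranchRoots(*roots)
    if len(roots) == 1:
        raise ValueError(f"w={w}: single root {roots[0]:.4f}; outside the bistable range")
    if len(roots) == 2:
        raise ValueError(f"w={w}: fold point (2 roots); shrink the w range")
    raise ValueError(f"w={w}: unexpected root count {len(roots)}")


def barrier(w: float, side: str, slice_: Optional[PotentialSlice] = None,
            p: Optional[NeuronParams] = None) -> float:
    """Energy barrier dU^side(w) = U(v_mid) - U(v_side), side in {left, right}.

    Computed by adaptive quadrature of -drift from the well to the saddle,
    so the additive constant of U cancels by construction.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    s = slice_ if slice_ is not None else isolated_slice(w, p)
    r = branch_roots(w, s)
    v_from = r.v_left if side == "left" else r.v_right
    val, _err = sp_integrate.quad(lambda x: -s.drift(x), v_from, r.v_mid, limit=200)
    return float(val)


def bistable_w_range(
    slice_factory: Callable[[float], PotentialSlice],
    w_lo: float = 0.0,
    w_hi: float = 1.0,
    n: int = 200,
) -> Tuple[float, float]:
    """Approximate (w_min, w_max) of the three-root (bistable) interval."""
    ws = np.linspace(w_lo, w_hi, n)
    ok = []
    for w in ws:
        try:
            branch_roots(w, slice_factory(w))
            ok.append(w)
        except ValueError:
            continue
    if not ok:
        raise ValueError("no bistable w found in the scanned range")
    return float(min(ok)), float(max(ok))


@dataclass
class BarrierProfile:
    """Tabulated barriers over w, with the barrier-equality point.

    ``w_star`` solves dU_left(w) = dU_right(w); ``f_value`` is the common
    barrier height there (the upper edge of the SISR noise window).
    """

    w: np.ndarray
    du_left: np.ndarray
    du_right: np.ndarray
    w_star: float
    f_value: float


def barrier_profile(
    w_range: Optional[Tuple[float, float]] = None,
    n: int = 120,
    slice_factory: Optional[Callable[[float], PotentialSlice]] = None,
    p: Optional[NeuronParams] = None,
) -> BarrierProfile:
    """Tabulate both barriers over the bistable w range and locate w*.

    Defaults to the isolated neuron.  The equality point is found by Brent
    bisection of dU_left - dU_right, which must change sign exactly once on
    the tabulated range.
    """
    factory = slice_factory or (lambda w: isolated_slice(w, p))
    if w_range is None:
        lo, hi = bistable_w_range(factory)
        # stay strictly inside the fold points
        span = hi - lo
        w_range = (lo + 0.02 * span, hi - 0.02 * span)
    ws = np.linspace(w_range[0], w_range[1], n)
    dul = np.empty(n)
    dur = np.empty(n)
    for i, w in enumerate(ws):
        s = factory(float(w))
        r = branch_roots(float(w), s)
        u_mid_minus = lambda v_from: sp_integrate.quad(
            lambda x: -s.drift(x), v_from, r.v_mid, limit=200
        )[0]
        dul[i] = u_mid_minus(r.v_left)
        dur[i] = u_mid_minus(r.v_right)
    diff = dul - dur
    sc = np.nonzero(np.sign(diff[:-1]) * np.sign(diff[1:]) < 0)[0]
    if len(sc) == 0:
        raise ValueError("no barrier-equality point in the given w range")
    i = sc[0]

    def gap(w: float) -> float:
        s = factory(w)
        r = branch_roots(w, s)
        f = lambda x: -s.drift(x)
        l = sp_integrate.quad(f, r.v_left, r.v_mid, limit=200)[0]
        rr = sp_integrate.quad(f, r.v_right, r.v_mid, limit=200)[0]
        return l - rr

    w_star = float(optimize.brentq(gap, ws[i], ws[i + 1], xtol=1e-10))
    f_value = barrier(w_star, "left", factory(w_star))
    return BarrierProfile(w=ws, du_left=dul, du_right=dur, w_star=w_star, f_value=f_value)


@dataclass(frozen=True)
class SigmaBounds:
    sigma_min: float
    sigma_max: float
    epsilon: float
    delta_u_left_at_we: float
    f_value: float


def sigma_bounds(
    epsilon: float,
    profile: BarrierProfile,
    w_e: float,
    slice_factory: Optional[Callable[[float], PotentialSlice]] = None,
    p: Optional[NeuronParams] = None,
) -> SigmaBounds:
    """Predicted SISR noise window [sigma_min, sigma_max] at a given eps.

    sigma_min = sqrt(2 dU_left(w_e) / ln(1/eps)),
    sigma_max = sqrt(2 F / ln(1/eps)).
    Raises if dU_left(w_e) exceeds F (no window).
    """
    if not (0.0 < epsilon < 1.0):
        raise ValueError("epsilon must be in (0, 1)")
    factory = slice_factory or (lambda w: isolated_slice(w, p))
    du_l = barrier(w_e, "left", factory(w_e))
    if du_l > profile.f_value:
        raise ValueError("dU_left(w_e) > F: no SISR noise window")
    log_term = math.log(1.0 / epsilon)
    return SigmaBounds(
        sigma_min=math.sqrt(2.0 * du_l / log_term),
        sigma_max=math.sqrt(2.0 * profile.f_value / log_term),
        epsilon=epsilon,
        delta_u_left_at_we=du_l,
        f_value=profile.f_value,
    )
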