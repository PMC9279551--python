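"""Dimensionless Morris-Lecar vector field and its parameterization.

The model is the nondimensional, type-II excitable Morris-Lecar neuron

    dv/dt = f(v, w) = g_c m_inf(v)(1 - v) + g_l (v_l - v) + g_k w (v_k - v)
    dw/dt = eps * g(v, w) = eps * cosh((v - v_3)/v_4) * (w_inf(v) - w)

with sigmoidal steady-state activations m_inf, w_inf.  ``v`` is the fast
membrane potential, ``w`` the slow recovery (fraction of open K+ channels),
``eps`` the timescale separation and ``v_l`` the leak reversal level acting
as the Hopf-bifurcation (excitability) parameter.  This module is the single
source of truth for the model constants; coupling currents enter only
through the generic additive ``i_ext`` hook.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from typing import Tuple

import numpy as np

__all__ = [
    "NeuronParams",
    "StatePoint",
    "activation_m",
    "activation_w",
    "ml_drift",
    "ml_jacobian",
    "v_nullcline_w",
    "V_SANITY",
    "W_SANITY",
]

# Sanity bands used by the integrator to flag blow-up: the model's physical
# voltage bound -1.4 < v < 2.5 widened by a 20% margin of its span, and a
# gating-like band for w.
_V_LO, _V_HI = -1.4, 2.5
_MARGIN = 0.2 * (_V_HI - _V_LO)
V_SANITY = (_V_LO - _MARGIN, _V_HI + _MARGIN)
W_SANITY = (-0.2, 1.2)


@dataclass(frozen=True)
class NeuronParams:
    """Constants of the dimensionless Morris-Lecar neuron.

    Defaults are the study's reference parameter set; ``v_l`` below the
    Hopf value keeps the isolated neuron excitable.
    """

    g_c: float = 1.0
    g_k: float = 1.0
    g_l: float = 0.1
    v_k: float = -2.0
    v_1: float = 0.0
    v_2: float = 0.36
    v_3: float = -0.2
    v_4: float = 0.52
    v_l: float = 1.515
    epsilon: float = 0.0005

    def __post_init__(self) -> None:
        if not (self.v_2 > 0 and self.v_4 > 0):
            raise ValueError("activation slope scales v_2, v_4 must be > 0")
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError("epsilon must lie in (0, 1)")

    def with_(self, **kw) -> "NeuronParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronParams":
        return cls(**d)


@dataclass(frozen=True)
class StatePoint:
    """A point (v, w) in the single-neuron phase plane."""

    v: float
    w: float

    def as_array(self) -> np.ndarray:
        return np.array([self.v, self.w], dtype=float)


def activation_m(v, p: NeuronParams):
    """Instantaneous Ca2+ activation m_inf(v) = (1 + tanh((v - v_1)/v_2))/2."""
    return 0.5 * (1.0 + np.tanh((v - p.v_1) / p.v_2))


def activation_w(v, p: NeuronParams):
    """Steady-state K+ activation w_inf(v) = (1 + tanh((v - v_3)/v_4))/2."""
    return 0.5 * (1.0 + np.tanh((v - p.v_3) / p.v_4))


def ml_drift(s: StatePoint, p: NeuronParams, i_ext: float = 0.0) -> Tuple[float, float]:
    """Deterministic drift (dv/dt, dw/dt) at state ``s``.

    ``i_ext`` is a generic additive current through which all synaptic,
    autaptic and multiplexing inputs enter the v-equation.
    """
    v, w = s.v, s.w
    dv = (
        p.g_c * activation_m(v, p) * (1.0 - v)
        + p.g_l * (p.v_l - v)
        + p.g_k * w * (p.v_k - v)
        + i_ext
    )
    dw = p.epsilon * math.cosh((v - p.v_3) / p.v_4) * (activation_w(v, p) - w)
    return dv, dw


def ml_jacobian(s: StatePoint, p: NeuronParams) -> np.ndarray:
    """Analytic Jacobian of (f, eps*g) at ``s`` (closed-form partials)."""
    v, w = s.v, s.w
    th_m = math.tanh((v - p.v_1) / p.v_2)
    m = 0.5 * (1.0 + th_m)
    dm = 0.5 * (1.0 - th_m * th_m) / p.v_2
    x = (v - p.v_3) / p.v_4
    th_w = math.tanh(x)
    w_inf = 0.5 * (1.0 + th_w)
    dw_inf = 0.5 * (1.0 - th_w * th_w) / p.v_4
    ch, sh = math.cosh(x), math.sinh(x)

    f_v = p.g_c * (dm * (1.0 - v) - m) - p.g_l - p.g_k * w
    f_w = p.g_k * (p.v_k - v)
    g_v = p.epsilon * (sh / p.v_4 * (w_inf - w) + ch * dw_inf)
    g_w = -p.epsilon * ch
    return np.array([[f_v, f_w], [g_v, g_w]])


def v_nullcline_w(v, p: NeuronParams):
    """The v-nullcline solved for w: f(v, w) = 0  =>  w(v).

    Single-valued in v (the coefficient of w never vanishes for v > v_k);
    S-shaped over the physical voltage range in the excitable regime.
    """
    v = np.asarray(v, dtype=float)
    num = p.g_c * activation_m(v, p) * (1.0 - v) + p.g_l * (p.v_l - v)
    den = p.g_k * (v - p.v_k)
    return num / den
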