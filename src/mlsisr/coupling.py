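"""Synaptic, autaptic and multiplexing coupling, and full-network drift.

Coupling currents entering a neuron's voltage equation:

* electrical (gap junction / electrical autapse / electrical multiplex):
      kappa * (v_source(t - tau) - v_target(t))
* chemical (directed, sigmoidally gated by the delayed presynaptic voltage):
      +/- kappa * (v_target(t) - v_syn) * Gamma(v_source(t - tau))
  with Gamma(v) = 1 / (1 + exp(-lambda (v - theta_syn))).  With
  v_syn = -1.5 below the reachable voltage range, the prefactor is always
  positive, so the stored nonnegative strength plus an explicit polarity
  fixes the sign: + excitatory, - inhibitory.

A network is one or two 3-neuron motif layers; layers are joined only
between replica neurons (multiplexing).  ``assemble_drift`` builds the
delayed deterministic drift of the whole network; ``compile_edges`` lowers a
NetworkSpec to flat arrays consumed by the compiled integrator kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import yaml

from .params import NeuronParams, StatePoint, ml_drift

__all__ = [
    "ChemicalConstants",
    "SynapseSpec",
    "MotifTopology",
    "LayerSpec",
    "NetworkSpec",
    "sigmoid_gate",
    "electrical_term",
    "chemical_term",
    "assemble_drift",
    "compile_edges",
    "motif_preset",
    "preset_names",
]

# Edge kind codes shared with the integrator kernel.
KIND_ELECTRICAL = 0
KIND_CHEMICAL = 1
KIND_ELECTRICAL_AS_PRINTED = 2


@dataclass(frozen=True)
class ChemicalConstants:
    """Constants of the sigmoidal chemical-synapse gate."""

    lambda_slope: float = 5.0
    theta_syn: float = 0.0
    v_syn: float = -1.5

    def __post_init__(self) -> None:
        if self.lambda_slope <= 0:
            raise ValueError("lambda_slope must be > 0")
        if self.v_syn >= -1.4:
            raise ValueError("v_syn must lie below the reachable voltage range (< -1.4)")


@dataclass(frozen=True)
class SynapseSpec:
    """One coupling element: kind, nonnegative strength, delay, polarity.

    ``polarity`` is meaningful for chemical synapses only; the sign is
    applied at assembly (+strength excitatory, -strength inhibitory).
    """

    kind: str  # "electrical" | "chemical"
    strength: float
    delay: float = 0.0
    polarity: str = "excitatory"

    def __post_init__(self) -> None:
        if self.kind not in ("electrical", "chemical"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if self.strength < 0:
            raise ValueError("strength must be >= 0 (sign comes from polarity)")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if self.polarity not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def signed_strength(self) -> float:
        if self.kind == "chemical" and self.polarity == "inhibitory":
            return -self.strength
        return self.strength


def _load_presets() -> Dict[str, np.ndarray]:
    text = resources.files("mlsisr").joinpath("motif_presets.yaml").read_text()
    data = yaml.safe_load(text)
    return {k: np.asarray(v, dtype=int) for k, v in data["presets"].items()}


_PRESETS = _load_presets()


def preset_names() -> List[str]:
    return sorted(_PRESETS)


def motif_preset(name: str) -> np.ndarray:
    """Adjacency matrix of a named preset (copy)."""
    try:
        return _PRESETS[name].copy()
    except KeyError:
        raise KeyError(f"unknown motif preset {name!r}; known: {preset_names()}") from None


@dataclass(frozen=True)
class MotifTopology:
    """3x3 binary adjacency; G[i][j]=1 means i receives input from j."""

    adjacency: np.ndarray
    preset_name: str = "custom"

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=int)
        if a.shape != (3, 3):
            raise ValueError("adjacency must be 3x3")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        if np.trace(a) != 0:
            raise ValueError("adjacency diagonal must be zero (self-loops are autapses)")
        object.__setattr__(self, "adjacency", a)

    @classmethod
    def from_preset(cls, name: str) -> "MotifTopology":
        return cls(adjacency=motif_preset(name), preset_name=name)

    @property
    def in_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def is_symmetric(self) -> bool:
        return bool((self.adjacency == self.adjacency.T).all())


@dataclass(frozen=True)
class LayerSpec:
    """One motif layer: neuron parameters, topology, intra-layer synapse,
    optional per-neuron autapses, and the layer noise amplitude."""

    params: NeuronParams = field(default_factory=NeuronParams)
    topology: Optional[MotifTopology] = None
    synapse: Optional[SynapseSpec] = None
    autapses: Dict[int, SynapseSpec] = field(default_factory=dict)
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if (self.topology is None) != (self.synapse is None):
            if self.synapse is not None and self.synapse.strength != 0:
                raise ValueError("intra-layer synapse given without a topology")
        for i in self.autapses:
            if i not in (0, 1, 2):
                raise ValueError("autapse index must be 0, 1 or 2")
        if self.topology is not None and self.synapse is not None:
            if self.synapse.kind == "electrical" and not self.topology.is_symmetric():
                raise ValueError("electrical (gap-junction) topology must be symmetric")


@dataclass(frozen=True)
class NetworkSpec:
    """One or two motif layers plus an optional multiplex coupling.

    Within a layer all three neurons share the same noise amplitude
    (sigma_{p,1} = sigma_{p,2} = sigma_{p,3}).  ``n_neurons`` is 3 per
    layer; a bare single neuron is a layer with no topology.
    """

    layers: Tuple[LayerSpec, ...]
    multiplex: Optional[SynapseSpec] = None
    chemical: ChemicalConstants = field(default_factory=ChemicalConstants)
    electrical_convention: str = "conventional"  # or "as_printed"
    neurons_per_layer: int = 3

    def __post_init__(self) -> None:
        if isinstance(self.layers, list):
            object.__setattr__(self, "layers", tuple(self.layers))
        if len(self.layers) not in (1, 2):
            raise ValueError("1 or 2 layers supported")
        if len(self.layers) == 2 and self.multiplex is None:
            raise ValueError("a 2-layer spec requires a multiplex SynapseSpec")
        if len(self.layers) == 1 and self.multiplex is not None:
            raise ValueError("multiplex coupling requires 2 layers")
        if self.electrical_convention not in ("conventional", "as_printed"):
            raise ValueError("electrical_convention: 'conventional' | 'as_printed'")
        if self.neurons_per_layer not in (1, 3):
            raise ValueError("neurons_per_layer must be 1 or 3")
        if self.neurons_per_layer == 1:
            for lay in self.layers:
                if lay.topology is not None:
                    raise ValueError("single-neuron layer cannot carry a topology")

    @property
    def n_neurons(self) -> int:
        return self.neurons_per_layer * len(self.layers)

    @property
    def sigmas(self) -> np.ndarray:
        return np.repeat([lay.noise_sigma for lay in self.layers], self.neurons_per_layer)

    def with_sigma(self, sigma: float) -> "NetworkSpec":
        """Same network with every layer's noise amplitude set to ``sigma``."""
        new_layers = tuple(
            LayerSpec(l.params, l.topology, l.synapse, dict(l.autapses), sigma)
            for l in self.layers
        )
        return NetworkSpec(
            new_layers, self.multiplex, self.chemical,
            self.electrical_convention, self.neurons_per_layer,
        )

    @classmethod
    def single_neuron(
        cls,
        params: Optional[NeuronParams] = None,
        autapse: Optional[SynapseSpec] = None,
        noise_sigma: float = 0.0,
        chemical: Optional[ChemicalConstants] = None,
    ) -> "NetworkSpec":
        lay = LayerSpec(
            params=params or NeuronParams(),
            autapses={0: autapse} if autapse else {},
            noise_sigma=noise_sigma,
        )
        return cls(layers=(lay,), chemical=chemical or ChemicalConstants(),
                   neurons_per_layer=1)

    @classmethod
    def motif(
        cls,
        preset: str,
        synapse: SynapseSpec,
        params: Optional[NeuronParams] = None,
        autapses: Optional[Dict[int, SynapseSpec]] = None,
        noise_sigma: float = 0.0,
        **kw,
    ) -> "NetworkSpec":
        lay = LayerSpec(
            params=params or NeuronParams(),
            topology=MotifTopology.from_preset(preset),
            synapse=synapse,
            autapses=autapses or {},
            noise_sigma=noise_sigma,
        )
        return cls(layers=(lay,), **kw)


def sigmoid_gate(v_pre_delayed, c: ChemicalConstants):
    """Gamma(v) = 1/(1 + exp(-lambda (v - theta_syn))), in (0, 1)."""
    return 1.0 / (1.0 + np.exp(-c.lambda_slope * (np.asarray(v_pre_delayed, float) - c.theta_syn)))


def electrical_term(delayed_source_v: float, target_v: float) -> float:
    """Diffusive electrical current (delayed source minus present target)."""
    return delayed_source_v - target_v


def chemical_term(target_v: float, delayed_source_v: float, c: ChemicalConstants) -> float:
    """Unsigned chemical current (v_target - v_syn) * Gamma(v_source(t-tau)).

    Always >= 0 for reachable voltages; the drift applies the polarity sign.
    Raises if the target voltage has fallen to the reversal potential, which
    signals a diverged simulation rather than a physical state.
    """
    if target_v <= c.v_syn:
        raise ValueError(
            f"target_v={target_v} <= v_syn={c.v_syn}: outside the reachable voltage range"
        )
    return (target_v - c.v_syn) * float(sigmoid_gate(delayed_source_v, c))


# ---------------------------------------------------------------------------
# Edge compilation: lower a NetworkSpec to flat arrays (src, dst, kind,
# signed weight, delay) shared by the reference drift and the kernel.
# ---------------------------------------------------------------------------

def compile_edges(spec: NetworkSpec):
    """Flatten all coupling terms of ``spec`` into parallel edge arrays.

    Returns (src, dst, kind, weight, delay) with global neuron indices
    layer*neurons_per_layer + i.  Chemical weights carry the polarity sign.
    """
    src: List[int] = []
    dst: List[int] = []
    kind: List[int] = []
    weight: List[float] = []
    delay: List[float] = []

    npl = spec.neurons_per_layer
    elec_kind = (
        KIND_ELECTRICAL
        if spec.electrical_convention == "conventional"
        else KIND_ELECTRICAL_AS_PRINTED
    )

    def add(s: int, d: int, syn: SynapseSpec, electrical_code: int) -> None:
        if syn.strength == 0:
            return
        src.append(s)
        dst.append(d)
        kind.append(electrical_code if syn.kind == "electrical" else KIND_CHEMICAL)
        weight.append(syn.signed_strength)
        delay.append(syn.delay)

    for p, lay in enumerate(spec.layers):
        base = p * npl
        if lay.topology is not None and lay.synapse is not None:
            g = lay.topology.adjacency
            for i in range(3):
                for j in range(3):
                    if g[i, j]:
                        add(base + j, base + i, lay.synapse, elec_kind)
        for i, aut in lay.autapses.items():
            # Autapses are self-edges; the printed autapse form is
            # delayed-self-minus-self, identical under both conventions.
            add(base + i, base + i, aut, KIND_ELECTRICAL)
    if spec.multiplex is not None:
        for i in range(npl):
            # Replica-to-replica, both directions; the multiplex electrical
            # form is delayed-other-minus-self in both equations.
            add(npl + i, i, spec.multiplex, KIND_ELECTRICAL)
            add(i, npl + i, spec.multiplex, KIND_ELECTRICAL)

    return (
        np.asarray(src, dtype=np.int64),
        np.asarray(dst, dtype=np.int64),
        np.asarray(kind, dtype=np.int64),
        np.asarray(weight, dtype=np.float64),
        np.asarray(delay, dtype=np.float64),
    )


def coupling_currents(
    spec: NetworkSpec,
    v_now: np.ndarray,
    history: Callable[[int, float], float],
) -> np.ndarray:
    """Per-neuron summed coupling current given present voltages and a
    history accessor ``history(neuron_index, lag) -> v``."""
    src, dst, kind, weight, delay = compile_edges(spec)
    cur = np.zeros(spec.n_neurons)
    c = spec.chemical
    for e in range(len(src)):
        s, d = int(src[e]), int(dst[e])
        if kind[e] == KIND_ELECTRICAL:
            cur[d] += weight[e] * (history(s, delay[e]) - v_now[d])
        elif kind[e] == KIND_ELECTRICAL_AS_PRINTED:
            cur[d] += weight[e] * (history(d, delay[e]) - v_now[s])
        else:
            gate = 1.0 / (1.0 + math.exp(-c.lambda_slope * (history(s, delay[e]) - c.theta_syn)))
            cur[d] += weight[e] * (v_now[d] - c.v_syn) * gate
    return cur


def assemble_drift(spec: NetworkSpec):
    """Build the delayed deterministic drift of the full network.

    Returns ``drift(states, history, t) -> (n, 2) array`` where ``states``
    is an (n, 2) array of (v, w) rows and ``history(i, lag)`` returns
    neuron i's voltage at time t - lag.  With all couplings at zero this
    reduces exactly to the isolated-neuron drift componentwise.
    """
    params = [lay.params for lay in spec.layers for _ in range(spec.neurons_per_layer)]

    def drift(states: np.ndarray, history: Callable[[int, float], float], t: float = 0.0):
        states = np.asarray(states, dtype=float)
        cur = coupling_currents(spec, states[:, 0], history)
        out = np.empty_like(states)
        for i in range(spec.n_neurons):
            dv, dw = ml_drift(StatePoint(states[i, 0], states[i, 1]), params[i], i_ext=cur[i])
            out[i, 0] = dv
            out[i, 1] = dw
        return out

    return drift
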