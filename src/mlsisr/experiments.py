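"""Config-driven experiments: CV-noise sweeps, enhancement maps, targets.

Each experiment reproduces one of the study's computations at a configurable
scale.  The reference (full) scale is a horizon of 3e5 time units with 6
realizations per noise amplitude; the package default is the scaled-down
desk protocol (3e4 time units, 3 realizations for curves; shorter horizons,
2 realizations and coarse parameter grids for two-dimensional CV_min maps),
with the Monte-Carlo uncertainty reported alongside.

The two SISR-enhancement strategies are first-class experiments:

* autapse attachment — an electrical or excitatory chemical autapse on the
  highest in-degree neuron of a chemically coupled motif;
* multiplexing — joining the motif to a second motif layer through
  replica-neuron (electrical or inhibitory chemical) links and scanning the
  multiplexing strength-delay plane, restricted to its excitable region.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field, asdict
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import __version__
from .analysis import (
    classify_excitability,
    find_fixed_point,
    hopf_value,
    network_fixed_point,
    oscillation_onset,
)
from .coupling import LayerSpec, MotifTopology, NetworkSpec, SynapseSpec
from .integrate import SimGrid
from .params import NeuronParams
from .spikes import CVCurve, cv_over_sigma
from .theory import barrier_profile

__all__ = [
    "ExperimentConfig",
    "RunManifest",
    "CVMap",
    "default_sigma_grid",
    "multiplex_spec",
    "run_cv_sweep",
    "run_cvmin_map",
    "TARGETS",
    "reproduce_target",
    "EXPERIMENTS",
]

# 20 log-spaced noise amplitudes bracketing the theoretical SISR window
# [sigma_min, sigma_max] of the isolated neuron at eps = 5e-4.
SIGMA_GRID_DEFAULT = tuple(np.geomspace(1e-4, 3e-1, 20))

# Caption parameters of the multiplex experiments: intra-layer inhibitory
# chemical coupling (strength, delay) for the lower (poor-SISR) and upper
# (high-SISR) motifs.
LOWER_MOTIF_COUPLING = (1.5, 10.0)
UPPER_MOTIF_COUPLING = (0.05, 20.0)

# Default coarse scan grids for the enhancement maps (strength, delay).
# The multiplex grids sample the excitable part of each plane: electrical
# multiplexing admits excitability only at weak coupling / short delay,
# inhibitory chemical multiplexing at weak-to-moderate coupling with long
# delays (cells failing the deterministic precheck are masked either way).
MULTIPLEX_MAP_GRIDS = {
    "electrical": ((0.25, 0.5), (0.5, 2.5, 5.0)),
    "chemical": ((0.05, 0.15, 0.25), (10.0, 15.0, 20.0)),
}
# the heterogeneous C3-C2 pair admits excitability only at much weaker
# inhibitory multiplexing than the homogeneous C2-C2 pair
MULTIPLEX_MAP_GRID_C2C3_CHEMICAL = ((0.01, 0.02, 0.03), (10.0, 15.0, 20.0))
AUTAPSE_MAP_GRID = ((0.25, 0.75, 1.5), (2.5, 10.0, 20.0))
MAP_KAPPA_GRID = AUTAPSE_MAP_GRID[0]
MAP_TAU_GRID = AUTAPSE_MAP_GRID[1]
# noise amplitudes bracketing the observed CV minima of the coupled systems
MAP_SIGMA_GRID = tuple(np.geomspace(8e-3, 1.2e-1, 6))
MAP_GRID_DEFAULT = SimGrid(dt=0.008, t_total=2.0e4, n_realizations=2, seed=0)


def default_sigma_grid(n: int = 20) -> np.ndarray:
    return np.geomspace(1e-4, 3e-1, n)


@dataclass
class ExperimentConfig:
    """One experiment: a network template, grids and a scale factor."""

    experiment_id: str
    spec: NetworkSpec
    grid: SimGrid = field(default_factory=SimGrid)
    sigma_values: Sequence[float] = SIGMA_GRID_DEFAULT
    neurons: Optional[Sequence[int]] = None  # CV evaluated on this subset
    # for maps: factory building the network of one (kappa, tau) cell
    cell_factory: Optional[Callable[[float, float], NetworkSpec]] = None
    kappa_grid: Sequence[float] = MAP_KAPPA_GRID
    tau_grid: Sequence[float] = MAP_TAU_GRID
    precheck: bool = True


@dataclass
class RunManifest:
    """Everything needed to re-run an experiment bit-identically."""

    experiment_id: str
    config: dict
    seed: int
    package_version: str
    python_version: str
    timestamp: float
    outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def _manifest(cfg: ExperimentConfig, outputs: dict) -> RunManifest:
    from .io import spec_to_dict

    return RunManifest(
        experiment_id=cfg.experiment_id,
        config=dict(
            network=spec_to_dict(cfg.spec),
            grid=asdict(cfg.grid),
            sigma_values=[float(s) for s in cfg.sigma_values],
            neurons=list(cfg.neurons) if cfg.neurons is not None else None,
            kappa_grid=[float(k) for k in cfg.kappa_grid],
            tau_grid=[float(t) for t in cfg.tau_grid],
        ),
        seed=cfg.grid.seed,
        package_version=__version__,
        python_version=platform.python_version(),
        timestamp=time.time(),
        outputs=outputs,
    )


def multiplex_spec(
    lower_preset: str = "C2",
    upper_preset: str = "C2",
    mult_kind: str = "electrical",
    mult_strength: float = 0.1,
    mult_delay: float = 2.5,
    mult_polarity: str = "inhibitory",
    lower_coupling: Tuple[float, float] = LOWER_MOTIF_COUPLING,
    upper_coupling: Tuple[float, float] = UPPER_MOTIF_COUPLING,
    params: Optional[NeuronParams] = None,
) -> NetworkSpec:
    """Two-layer multiplex network: lower motif = layer 0 (neurons 0-2).

    Both layers carry inhibitory chemical intra-layer synapses at the
    caption parameters; replica neurons are joined by the requested
    multiplexing synapse (electrical, or chemical with the given polarity).
    """
    p = params or NeuronParams()
    lower = LayerSpec(
        params=p,
        topology=MotifTopology.from_preset(lower_preset),
        synapse=SynapseSpec("chemical", lower_coupling[0], lower_coupling[1], "inhibitory"),
    )
    upper = LayerSpec(
        params=p,
        topology=MotifTopology.from_preset(upper_preset),
        synapse=SynapseSpec("chemical", upper_coupling[0], upper_coupling[1], "inhibitory"),
    )
    mult = SynapseSpec(mult_kind, mult_strength, mult_delay, mult_polarity)
    return NetworkSpec(layers=(lower, upper), multiplex=mult)


def run_cv_sweep(cfg: ExperimentConfig) -> Tuple[CVCurve, RunManifest]:
    """One CV-versus-noise curve with a deterministic excitability precheck.

    Aborts if the zero-noise network is oscillatory (noise-induced
    coherence would be confounded by deterministic oscillation).
    """
    if cfg.precheck:
        res = classify_excitability(cfg.spec.with_sigma(0.0))
        if res.classification != "excitable":
            raise RuntimeError(
                f"{cfg.experiment_id}: zero-noise network is {res.classification} "
                f"(mean ISI {res.mean_isi}); refusing the stochastic sweep"
            )
    initial = network_fixed_point(cfg.spec.with_sigma(0.0))
    curve = cv_over_sigma(cfg.spec, cfg.grid, cfg.sigma_values,
                          neurons=cfg.neurons, initial=initial)
    man = _manifest(cfg, outputs=dict(
        cv_min=(float(curve.cv_min) if curve.defined_mask.any() else None),
        sigma_at_min=(float(curve.sigma_at_min) if curve.defined_mask.any() else None),
        n_defined_points=int(curve.defined_mask.sum()),
    ))
    return curve, man


@dataclass
class CVMap:
    """CV_min over a 2-D (strength, delay) plane with excitability masking."""

    kappa_grid: np.ndarray
    tau_grid: np.ndarray
    cv_min: np.ndarray  # NaN where oscillatory/failed/undefined
    classification: np.ndarray  # "excitable" | "oscillatory" | "failed"

    @property
    def best(self) -> float:
        if np.isnan(self.cv_min).all():
            raise ValueError("no defined cell in the map")
        return float(np.nanmin(self.cv_min))

    @property
    def best_cell(self) -> Tuple[float, float]:
        idx = np.unravel_index(np.nanargmin(self.cv_min), self.cv_min.shape)
        return float(self.kappa_grid[idx[0]]), float(self.tau_grid[idx[1]])

    def to_records(self) -> List[dict]:
        out = []
        for a, k in enumerate(self.kappa_grid):
            for b, t in enumerate(self.tau_grid):
                out.append(dict(kappa=float(k), tau=float(t),
                                classification=str(self.classification[a, b]),
                                cv_min=float(self.cv_min[a, b])))
        return out


def run_cvmin_map(cfg: ExperimentConfig) -> Tuple[CVMap, RunManifest]:
    """CV_min over the (kappa, tau) plane of ``cfg.cell_factory``.

    Each cell is prechecked deterministically; oscillatory cells are masked
    (never simulated with noise), failures are recorded and the map always
    completes.
    """
    if cfg.cell_factory is None:
        raise ValueError("map experiment needs a cell_factory")
    kg = np.asarray(list(cfg.kappa_grid), dtype=float)
    tg = np.asarray(list(cfg.tau_grid), dtype=float)
    cvm = np.full((len(kg), len(tg)), np.nan)
    cls = np.empty((len(kg), len(tg)), dtype=object)
    for a, k in enumerate(kg):
        for b, t in enumerate(tg):
            try:
                spec = cfg.cell_factory(float(k), float(t))
                res = classify_excitability(spec.with_sigma(0.0))
                cls[a, b] = res.classification
                if res.classification != "excitable":
                    continue
                initial = network_fixed_point(spec.with_sigma(0.0))
                curve = cv_over_sigma(spec, cfg.grid, cfg.sigma_values,
                                      neurons=cfg.neurons, initial=initial)
                if curve.defined_mask.any():
                    cvm[a, b] = curve.cv_min
            except Exception:
                cls[a, b] = "failed"
    man = _manifest(cfg, outputs=dict(
        best=(float(np.nanmin(cvm)) if not np.isnan(cvm).all() else None),
        n_excitable=int((cls == "excitable").sum()),
    ))
    return CVMap(kg, tg, cvm, cls), man


# ---------------------------------------------------------------------------
# Named experiment builders
# ---------------------------------------------------------------------------


def _cfg_single(eps: float = 0.0005, **kw) -> ExperimentConfig:
    spec = NetworkSpec.single_neuron(params=NeuronParams(epsilon=eps))
    return ExperimentConfig("single_neuron", spec, **kw)


def _cfg_motif(preset: str, kind: str, strength: float, delay: float,
               polarity: str = "inhibitory", **kw) -> ExperimentConfig:
    spec = NetworkSpec.motif(preset, SynapseSpec(kind, strength, delay, polarity))
    return ExperimentConfig(f"motif_{preset}", spec, **kw)


def _cfg_autapse_map(preset: str, autapse_kind: str, polarity: str = "excitatory",
                     **kw) -> ExperimentConfig:
    """Autapse enhancement: autapse on neuron 0 (highest in-degree)."""
    base_syn = SynapseSpec("chemical", *LOWER_MOTIF_COUPLING, "inhibitory")

    def factory(kappa: float, tau: float) -> NetworkSpec:
        aut = SynapseSpec(autapse_kind, kappa, tau, polarity)
        return NetworkSpec.motif(preset, base_syn, autapses={0: aut})

    cfg = ExperimentConfig(f"autapse_map_{preset}_{autapse_kind}",
                           NetworkSpec.motif(preset, base_syn),
                           cell_factory=factory, **kw)
    return cfg


def _cfg_multiplex_map(lower: str, upper: str, mult_kind: str,
                       mult_polarity: str = "inhibitory", **kw) -> ExperimentConfig:
    def factory(kappa: float, tau: float) -> NetworkSpec:
        return multiplex_spec(lower, upper, mult_kind, kappa, tau, mult_polarity)

    kg, tg = MULTIPLEX_MAP_GRIDS[mult_kind]
    kw.setdefault("kappa_grid", kg)
    kw.setdefault("tau_grid", tg)
    cfg = ExperimentConfig(
        f"multiplex_map_{lower}_{upper}_{mult_kind}",
        factory(kg[0], tg[0]),
        cell_factory=factory,
        neurons=(0, 1, 2),  # CV of the lower (poor-SISR) layer
        **kw,
    )
    return cfg


EXPERIMENTS: Dict[str, Callable[..., ExperimentConfig]] = {
    "fig5_single_neuron": _cfg_single,
    "fig7_electrical_autapse": lambda kappa=0.05, tau=5.0, **kw: ExperimentConfig(
        "single_neuron_electrical_autapse",
        NetworkSpec.single_neuron(autapse=SynapseSpec("electrical", kappa, tau)),
        **kw,
    ),
    "fig8_chemical_autapse": lambda kappa=0.05, tau=5.0, **kw: ExperimentConfig(
        "single_neuron_chemical_autapse",
        NetworkSpec.single_neuron(
            autapse=SynapseSpec("chemical", kappa, tau, "inhibitory")
        ),
        **kw,
    ),
    "fig13_C2": lambda **kw: _cfg_motif("C2", "chemical", *LOWER_MOTIF_COUPLING, **kw),
    "fig13_C3": lambda **kw: _cfg_motif("C3", "chemical", *LOWER_MOTIF_COUPLING, **kw),
    "fig14_autapse_enhancement_C2": lambda kind="chemical", **kw: _cfg_autapse_map(
        "C2", kind, **kw
    ),
    "fig15_autapse_enhancement_C3": lambda kind="chemical", **kw: _cfg_autapse_map(
        "C3", kind, **kw
    ),
    "fig16_multiplex_C2C2_electrical": lambda **kw: _cfg_multiplex_map(
        "C2", "C2", "electrical", **kw
    ),
    "fig16_multiplex_C2C2_chemical": lambda **kw: _cfg_multiplex_map(
        "C2", "C2", "chemical", **kw
    ),
    "fig17_multiplex_C2C3_electrical": lambda **kw: _cfg_multiplex_map(
        "C3", "C2", "electrical", **kw
    ),
    "fig17_multiplex_C2C3_chemical": lambda **kw: _cfg_multiplex_map(
        "C3", "C2", "chemical",
        **{
            "kappa_grid": MULTIPLEX_MAP_GRID_C2C3_CHEMICAL[0],
            "tau_grid": MULTIPLEX_MAP_GRID_C2C3_CHEMICAL[1],
            **kw,
        },
    ),
}


# ---------------------------------------------------------------------------
# Reference-value registry (reproduction harness)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetSpec:
    name: str
    description: str
    expected: float
    rel_tol: float
    compute: Callable[[int], Tuple[float, int]]  # seed -> (value, problem size)
    cmp: str = "eq"  # "eq" | "le"


def _t_hopf_onset(seed: int) -> Tuple[float, int]:
    r = oscillation_onset(0.0005)
    return r.v_hopf, 1

def _t_hopf_plateau(seed: int) -> Tuple[float, int]:
    a = hopf_value(1e-6).v_hopf
    b = hopf_value(1e-5).v_hopf
    if abs(a - b) > 1e-3:
        raise RuntimeError(f"no plateau: {a} vs {b}")
    return 0.5 * (a + b), 2

def _t_fixed_point_v(seed: int) -> Tuple[float, int]:
    return find_fixed_point(NeuronParams()).v_e, 1

def _t_w_star(seed: int) -> Tuple[float, int]:
    return barrier_profile().w_star, 1

def _t_f_value(seed: int) -> Tuple[float, int]:
    return barrier_profile().f_value, 1


def _sweep_cv_min(preset: str, seed: int) -> Tuple[float, int]:
    cfg = EXPERIMENTS[f"fig13_{preset}"](
        grid=SimGrid(dt=0.008, t_total=3.0e4, n_realizations=3, seed=seed),
        sigma_values=SIGMA_GRID_DEFAULT,
    )
    curve, _ = run_cv_sweep(cfg)
    return curve.cv_min, int(3.0e4 / 0.008) * 3

def _t_cv_min_c2(seed: int) -> Tuple[float, int]:
    return _sweep_cv_min("C2", seed)

def _t_cv_min_c3(seed: int) -> Tuple[float, int]:
    return _sweep_cv_min("C3", seed)


def _map_best(exp_name: str, seed: int) -> Tuple[float, int]:
    cfg = EXPERIMENTS[exp_name](
        grid=SimGrid(
            dt=MAP_GRID_DEFAULT.dt,
            t_total=MAP_GRID_DEFAULT.t_total,
            n_realizations=MAP_GRID_DEFAULT.n_realizations,
            seed=seed,
        ),
        sigma_values=MAP_SIGMA_GRID,
    )
    m, _ = run_cvmin_map(cfg)
    n = len(cfg.kappa_grid) * len(cfg.tau_grid)
    return m.best, n

def _t_multiplex_c2c2_electrical(seed: int) -> Tuple[float, int]:
    return _map_best("fig16_multiplex_C2C2_electrical", seed)

def _t_multiplex_c2c2_chemical(seed: int) -> Tuple[float, int]:
    return _map_best("fig16_multiplex_C2C2_chemical", seed)

def _t_multiplex_c2c3_chemical(seed: int) -> Tuple[float, int]:
    return _map_best("fig17_multiplex_C2C3_chemical", seed)


TARGETS: Dict[str, TargetSpec] = {
    t.name: t
    for t in [
        TargetSpec(
            "hopf_onset",
            "oscillation-onset value of v_l at eps=5e-4 (simulation bisection)",
            1.52010, 2e-2, _t_hopf_onset,
        ),
        TargetSpec(
            "hopf_plateau",
            "eigenvalue Hopf value of v_l, plateau over eps in [1e-6, 1e-5]",
            1.524, 1e-3 / 1.524, _t_hopf_plateau,
        ),
        TargetSpec(
            "fixed_point_v",
            "v-coordinate of the unique stable fixed point at v_l=1.515",
            -0.5767, 5e-4 / 0.5767, _t_fixed_point_v,
        ),
        TargetSpec(
            "barrier_equality_w",
            "recovery value w* where left and right energy barriers are equal",
            0.2662, 1e-3 / 0.2662, _t_w_star,
        ),
        TargetSpec(
            "barrier_equality_f",
            "common barrier height F at w*",
            0.059274, 2e-2, _t_f_value,
        ),
        TargetSpec(
            "cv_min_c2",
            "CV curve minimum, motif C2, inhibitory chemical (1.5, 10.0)",
            0.293, 0.05 / 0.293, _t_cv_min_c2, cmp="le",
        ),
        TargetSpec(
            "cv_min_c3",
            "CV curve minimum, motif C3, inhibitory chemical (1.5, 10.0)",
            0.232, 0.05 / 0.232, _t_cv_min_c3, cmp="le",
        ),
        TargetSpec(
            "multiplex_c2c2_electrical",
            "best-cell CV_min, lower C2 layer, electrical multiplexing scan",
            0.12, 0.05 / 0.12, _t_multiplex_c2c2_electrical, cmp="le",
        ),
        TargetSpec(
            "multiplex_c2c2_chemical",
            "best-cell CV_min, lower C2 layer, inhibitory chemical multiplexing",
            0.25, 0.05 / 0.25, _t_multiplex_c2c2_chemical, cmp="le",
        ),
        TargetSpec(
            "multiplex_c2c3_chemical",
            "best-cell CV_min, lower C3 layer, inhibitory chemical multiplexing",
            0.058, 0.05 / 0.058, _t_multiplex_c2c3_chemical, cmp="le",
        ),
    ]
}


def reproduce_target(
    name: str, seed: int = 0, expected_override: Optional[float] = None
) -> dict:
    """Recompute one registered reference quantity and compare.

    ``expected_override`` substitutes the registered reference value (used
    e.g. as a harness negative control).  For cmp="le" a computed value
    below the reference also passes (a deeper CV minimum is a stronger
    result).
    """
    if name not in TARGETS:
        raise KeyError(f"unknown target {name!r}; known: {sorted(TARGETS)}")
    t = TARGETS[name]
    expected = t.expected if expected_override is None else expected_override
    value, n = t.compute(seed)
    tol = abs(expected) * t.rel_tol
    if t.cmp == "le":
        passed = value <= expected + tol and value >= 0
    else:
        passed = abs(value - expected) <= tol
    return dict(
        name=name,
        description=t.description,
        value=float(value),
        expected=float(expected),
        tolerance=float(tol),
        cmp=t.cmp,
        passed=bool(passed),
        n=int(n),
        seed=int(seed),
    )
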