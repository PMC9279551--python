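"""Serialization: YAML configs, CSV tables, HDF5 trajectory containers."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .coupling import (
    ChemicalConstants,
    LayerSpec,
    MotifTopology,
    NetworkSpec,
    SynapseSpec,
)
from .integrate import SimGrid, Trajectory
from .params import NeuronParams

__all__ = [
    "spec_to_dict",
    "spec_from_dict",
    "save_config",
    "load_config",
    "curve_to_csv",
    "map_to_csv",
    "profile_to_csv",
    "bounds_to_json",
    "trajectory_to_csv",
    "save_trajectory",
    "load_trajectory",
]


def _synapse_to_dict(s: Optional[SynapseSpec]) -> Optional[dict]:
    return None if s is None else asdict(s)


def _synapse_from_dict(d: Optional[dict]) -> Optional[SynapseSpec]:
    return None if d is None else SynapseSpec(**d)


def spec_to_dict(spec: NetworkSpec) -> dict:
    """Plain-dict (YAML/JSON-ready) form of a NetworkSpec."""
    layers = []
    for lay in spec.layers:
        layers.append(
            dict(
                params=lay.params.to_dict(),
                topology=(
                    None
                    if lay.topology is None
                    else dict(
                        preset_name=lay.topology.preset_name,
                        adjacency=lay.topology.adjacency.tolist(),
                    )
                ),
                synapse=_synapse_to_dict(lay.synapse),
                autapses={str(i): _synapse_to_dict(a) for i, a in lay.autapses.items()},
                noise_sigma=lay.noise_sigma,
            )
        )
    return dict(
        layers=layers,
        multiplex=_synapse_to_dict(spec.multiplex),
        chemical=asdict(spec.chemical),
        electrical_convention=spec.electrical_convention,
        neurons_per_layer=spec.neurons_per_layer,
    )


def spec_from_dict(d: dict) -> NetworkSpec:
    layers = []
    for ld in d["layers"]:
        topo = ld.get("topology")
        if topo is not None:
            if isinstance(topo, str):
                topology = MotifTopology.from_preset(topo)
            else:
                topology = MotifTopology(
                    adjacency=np.asarray(topo["adjacency"], dtype=int),
                    preset_name=topo.get("preset_name", "custom"),
                )
        else:
            topology = None
        layers.append(
            LayerSpec(
                params=NeuronParams.from_dict(ld["params"]),
                topology=topology,
                synapse=_synapse_from_dict(ld.get("synapse")),
                autapses={
                    int(i): _synapse_from_dict(a)
                    for i, a in (ld.get("autapses") or {}).items()
                },
                noise_sigma=float(ld.get("noise_sigma", 0.0)),
            )
        )
    return NetworkSpec(
        layers=tuple(layers),
        multiplex=_synapse_from_dict(d.get("multiplex")),
        chemical=ChemicalConstants(**(d.get("chemical") or {})),
        electrical_convention=d.get("electrical_convention", "conventional"),
        neurons_per_layer=int(d.get("neurons_per_layer", 3)),
    )


def save_config(spec: NetworkSpec, path: Union[str, Path],
                grid: Optional[SimGrid] = None) -> None:
    doc = dict(network=spec_to_dict(spec))
    if grid is not None:
        doc["grid"] = asdict(grid)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: Union[str, Path]):
    doc = yaml.safe_load(Path(path).read_text())
    spec = spec_from_dict(doc["network"])
    grid = SimGrid(**doc["grid"]) if "grid" in doc else None
    return spec, grid


def curve_to_csv(curve, path: Union[str, Path]) -> None:
    pd.DataFrame(curve.to_records()).to_csv(path, index=False)


def map_to_csv(map_, path: Union[str, Path]) -> None:
    pd.DataFrame(map_.to_records()).to_csv(path, index=False)


def profile_to_csv(profile, path: Union[str, Path]) -> None:
    """Barrier profile as long-format CSV (w, du_left, du_right)."""
    pd.DataFrame(
        dict(w=profile.w, du_left=profile.du_left, du_right=profile.du_right)
    ).to_csv(path, index=False)


def bounds_to_json(bounds, path: Union[str, Path]) -> None:
    """SISR noise-window prediction as JSON."""
    import json
    from dataclasses import asdict as _asdict

    Path(path).write_text(json.dumps(_asdict(bounds), indent=2))


def trajectory_to_csv(traj: Trajectory, path: Union[str, Path]) -> None:
    """Recorded path as CSV (small runs only; columns t, v_i, w_i)."""
    cols = {"t": traj.t}
    for i in range(traj.n_neurons):
        cols[f"v_{i}"] = traj.v[:, i]
        cols[f"w_{i}"] = traj.w[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def save_trajectory(traj: Trajectory, path: Union[str, Path],
                    config_yaml: Optional[str] = None) -> None:
    """Persist a trajectory (time, v, w, spikes) to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=traj.t)
        f.create_dataset("v", data=traj.v)
        f.create_dataset("w", data=traj.w)
        g = f.create_group("spikes")
        for i, st in enumerate(traj.spike_times):
            g.create_dataset(str(i), data=st)
        f.attrs["dt"] = traj.dt
        f.attrs["realization"] = traj.realization
        f.attrs["seed_used"] = str(traj.seed_used)
        if config_yaml is not None:
            f.attrs["config"] = config_yaml


def load_trajectory(path: Union[str, Path]) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as f:
        spikes = [f["spikes"][k][()] for k in sorted(f["spikes"], key=int)]
        return Trajectory(
            t=f["time"][()],
            v=f["v"][()],
            w=f["w"][()],
            spike_times=spikes,
            dt=float(f.attrs["dt"]),
            seed_used=f.attrs["seed_used"],
            realization=int(f.attrs["realization"]),
        )
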