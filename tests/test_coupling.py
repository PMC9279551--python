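"""Synaptic/autaptic/multiplex coupling terms and full-network assembly."""

import math

import numpy as np
import pytest

from mlsisr.coupling import (
    ChemicalConstants,
    LayerSpec,
    MotifTopology,
    NetworkSpec,
    SynapseSpec,
    assemble_drift,
    chemical_term,
    compile_edges,
    electrical_term,
    motif_preset,
    preset_names,
    sigmoid_gate,
)
from mlsisr.io import spec_from_dict, spec_to_dict
from mlsisr.params import NeuronParams, StatePoint, ml_drift


class TestGateAndTerms:
    def test_gate_half_at_threshold(self):
        assert sigmoid_gate(0.0, ChemicalConstants()) == pytest.approx(0.5)

    def test_gate_hand_value(self):
        # lambda = 5, v = 0.2 -> 1/(1 + e^-1)
        assert sigmoid_gate(0.2, ChemicalConstants()) == pytest.approx(
            1.0 / (1.0 + math.exp(-1.0)), abs=1e-12
        )

    def test_gate_limits(self):
        c = ChemicalConstants()
        assert sigmoid_gate(-1e3, c) == pytest.approx(0.0, abs=1e-12)
        assert sigmoid_gate(1e3, c) == pytest.approx(1.0, abs=1e-12)

    def test_electrical_term(self):
        assert electrical_term(0.7, 0.7) == 0.0  # constant history
        assert electrical_term(-2.0 + 1.0, 1.0) == pytest.approx(-2.0)  # linear history

    def test_chemical_term_zero_at_reversal(self):
        c = ChemicalConstants()
        assert chemical_term(c.v_syn + 1e-12, 0.0, c) == pytest.approx(0.0, abs=1e-9)

    def test_chemical_term_closed_gate(self):
        assert chemical_term(0.0, -1e3, ChemicalConstants()) == pytest.approx(0.0, abs=1e-9)

    def test_chemical_term_hand_value(self):
        # (0 - (-1.5)) * Gamma(0) = 1.5 * 0.5
        assert chemical_term(0.0, 0.0, ChemicalConstants()) == pytest.approx(0.75)

    def test_chemical_term_rejects_diverged_target(self):
        with pytest.raises(ValueError):
            chemical_term(-1.6, 0.0, ChemicalConstants())


class TestPresets:
    def test_all_presets_valid(self):
        for name in preset_names():
            g = motif_preset(name)
            assert g.shape == (3, 3)
            assert np.trace(g) == 0
            assert set(np.unique(g)) <= {0, 1}

    def test_electrical_presets_symmetric(self):
        for name in ("E1", "E2"):
            g = motif_preset(name)
            assert (g == g.T).all()

    def test_c2_c3_highest_in_degree_is_neuron_one(self):
        for name in ("C2", "C3"):
            indeg = motif_preset(name).sum(axis=1)
            assert indeg[0] > indeg[1] and indeg[0] > indeg[2]

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            motif_preset("E9")

    def test_nonzero_diagonal_rejected(self):
        g = motif_preset("C2")
        g[1, 1] = 1
        with pytest.raises(ValueError):
            MotifTopology(g)


def _const_history(v_now):
    return lambda i, lag: float(v_now[i])


class TestAssembly:
    def test_zero_coupling_reduces_to_isolated(self, rng):
        spec = NetworkSpec.motif("C3", SynapseSpec("chemical", 0.0, 5.0, "inhibitory"))
        drift = assemble_drift(spec)
        for _ in range(3):
            states = np.column_stack(
                [rng.uniform(-1.0, 1.0, 3), rng.uniform(0.0, 0.6, 3)]
            )
            got = drift(states, _const_history(states[:, 0]), 0.0)
            for i in range(3):
                dv, dw = ml_drift(StatePoint(*states[i]), spec.layers[0].params)
                assert got[i, 0] == pytest.approx(dv, abs=1e-14)
                assert got[i, 1] == pytest.approx(dw, abs=1e-14)

    def test_identical_states_cancel_gap_junctions(self):
        spec = NetworkSpec.motif("E2", SynapseSpec("electrical", 0.8, 0.0))
        drift = assemble_drift(spec)
        states = np.tile([[0.1, 0.3]], (3, 1))
        got = drift(states, _const_history(states[:, 0]), 0.0)
        dv, dw = ml_drift(StatePoint(0.1, 0.3), spec.layers[0].params)
        assert np.allclose(got[:, 0], dv, atol=1e-14)

    def test_single_inhibitory_edge_hand_value(self):
        # neuron 1 receives one inhibitory chemical edge from neuron 0;
        # all voltages at 0: dv_1 = 0.6515 - 1.5 * 0.75 = -0.4735
        g = np.zeros((3, 3), dtype=int)
        g[1, 0] = 1
        lay = LayerSpec(
            params=NeuronParams(),
            topology=MotifTopology(g),
            synapse=SynapseSpec("chemical", 1.5, 0.0, "inhibitory"),
        )
        spec = NetworkSpec(layers=(lay,))
        drift = assemble_drift(spec)
        states = np.zeros((3, 2))
        got = drift(states, _const_history(states[:, 0]), 0.0)
        assert got[1, 0] == pytest.approx(-0.4735, abs=1e-12)
        assert got[0, 0] == pytest.approx(0.6515, abs=1e-12)

    def test_electrical_pair_currents_equal_and_opposite(self, rng):
        spec = NetworkSpec.motif("E1", SynapseSpec("electrical", 0.6, 0.0))
        drift = assemble_drift(spec)
        p = spec.layers[0].params
        states = np.column_stack([rng.uniform(-1, 1, 3), rng.uniform(0, 0.6, 3)])
        got = drift(states, _const_history(states[:, 0]), 0.0)
        iso = np.array(
            [ml_drift(StatePoint(*states[i]), p) for i in range(3)]
        )
        currents = got[:, 0] - iso[:, 0]
        # E1 chain: current into 0 from 1, into 2 from 1; neuron 1 gets both
        assert currents.sum() == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("preset", ["E1", "E2", "C1", "C2", "C3", "C7"])
    def test_assembly_matches_brute_force(self, preset, rng):
        kind = "electrical" if preset.startswith("E") else "chemical"
        syn = SynapseSpec(kind, 0.7, 3.0, "inhibitory")
        spec = NetworkSpec.motif(preset, syn)
        drift = assemble_drift(spec)
        g = motif_preset(preset)
        c = spec.chemical
        for _ in range(3):
            states = np.column_stack([rng.uniform(-1, 1, 3), rng.uniform(0, 0.6, 3)])
            past = rng.uniform(-1, 1, 3)  # delayed voltages
            hist = lambda i, lag: float(past[i]) if lag > 0 else float(states[i, 0])
            got = drift(states, hist, 0.0)
            for i in range(3):
                dv, dw = ml_drift(StatePoint(*states[i]), spec.layers[0].params)
                for j in range(3):
                    if not g[i, j]:
                        continue
                    if kind == "electrical":
                        dv += syn.strength * (past[j] - states[i, 0])
                    else:
                        gate = 1.0 / (1.0 + math.exp(-c.lambda_slope * past[j]))
                        dv += -syn.strength * (states[i, 0] - c.v_syn) * gate
                assert got[i, 0] == pytest.approx(dv, abs=1e-12)
                assert got[i, 1] == pytest.approx(dw, abs=1e-12)

    def test_polarity_contract(self, rng):
        # excitatory chemical input always raises dv/dt, inhibitory lowers it
        g = np.zeros((3, 3), dtype=int)
        g[1, 0] = 1
        for polarity, sign in (("excitatory", 1.0), ("inhibitory", -1.0)):
            lay = LayerSpec(
                params=NeuronParams(),
                topology=MotifTopology(g),
                synapse=SynapseSpec("chemical", 0.9, 0.0, polarity),
            )
            drift = assemble_drift(NetworkSpec(layers=(lay,)))
            for _ in range(20):
                states = np.column_stack(
                    [rng.uniform(-1.3, 2.4, 3), rng.uniform(0, 1, 3)]
                )
                got = drift(states, _const_history(states[:, 0]), 0.0)
                dv, _ = ml_drift(StatePoint(*states[1]), lay.params)
                assert sign * (got[1, 0] - dv) > 0

    def test_as_printed_electrical_convention_differs(self, rng):
        states = np.column_stack([rng.uniform(-1, 1, 3), rng.uniform(0, 0.6, 3)])
        past = rng.uniform(-1, 1, 3)
        hist = lambda i, lag: float(past[i]) if lag > 0 else float(states[i, 0])
        out = {}
        for conv in ("conventional", "as_printed"):
            spec = NetworkSpec.motif(
                "E1", SynapseSpec("electrical", 0.5, 2.0), electrical_convention=conv
            )
            out[conv] = assemble_drift(spec)(states, hist, 0.0)
        assert not np.allclose(out["conventional"], out["as_printed"])


class TestSpecValidation:
    def test_two_layers_require_multiplex(self):
        lay = LayerSpec(params=NeuronParams())
        with pytest.raises(ValueError):
            NetworkSpec(layers=(lay, lay))

    def test_multiplex_requires_two_layers(self):
        lay = LayerSpec(params=NeuronParams())
        with pytest.raises(ValueError):
            NetworkSpec(layers=(lay,), multiplex=SynapseSpec("electrical", 0.1))

    def test_negative_strength_rejected(self):
        with pytest.raises(ValueError):
            SynapseSpec("chemical", -0.5, 0.0, "inhibitory")

    def test_asymmetric_electrical_topology_rejected(self):
        g = np.zeros((3, 3), dtype=int)
        g[0, 1] = 1
        with pytest.raises(ValueError):
            LayerSpec(
                params=NeuronParams(),
                topology=MotifTopology(g),
                synapse=SynapseSpec("electrical", 0.5, 0.0),
            )

    def test_signed_strength(self):
        assert SynapseSpec("chemical", 2.0, 0.0, "inhibitory").signed_strength == -2.0
        assert SynapseSpec("chemical", 2.0, 0.0, "excitatory").signed_strength == 2.0
        assert SynapseSpec("electrical", 2.0, 0.0).signed_strength == 2.0


def test_spec_yaml_round_trip():
    from mlsisr.experiments import multiplex_spec

    spec = multiplex_spec("C2", "C3", "chemical", 0.3, 7.5, "inhibitory")
    spec2 = spec_from_dict(spec_to_dict(spec))
    assert spec_to_dict(spec2) == spec_to_dict(spec)
    e1 = compile_edges(spec)
    e2 = compile_edges(spec2)
    for a, b in zip(e1, e2):
        assert np.array_equal(a, b)
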