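"""Deterministic analysis: fixed points, Hopf bifurcation, excitability."""

import numpy as np
import pytest

from mlsisr.analysis import (
    classify_excitability,
    excitability_map,
    find_fixed_point,
    hopf_value,
    network_fixed_point,
    oscillation_onset,
)
from mlsisr.coupling import NetworkSpec, SynapseSpec
from mlsisr.params import (
    NeuronParams,
    StatePoint,
    activation_w,
    ml_drift,
    v_nullcline_w,
)


class TestFixedPoint:
    def test_reference_location(self, fixed_point):
        assert fixed_point.v_e == pytest.approx(-0.5767, abs=5e-4)
        assert fixed_point.w_e == pytest.approx(0.19019, abs=5e-4)
        assert fixed_point.stability == "stable"

    def test_drift_vanishes(self, fixed_point, params):
        dv, dw = ml_drift(StatePoint(fixed_point.v_e, fixed_point.w_e), params)
        assert np.hypot(dv, dw) < 1e-10

    def test_uniqueness_against_dense_scan(self, params):
        vs = np.linspace(-1.4, 2.5, 10_000)
        gap = v_nullcline_w(vs, params) - activation_w(vs, params)
        crossings = int(np.sum(np.diff(np.sign(gap)) != 0))
        assert crossings == 1

    def test_multiple_intersections_rejected(self):
        # lowering v_3 far enough deforms w_inf into triple intersection
        p = NeuronParams(v_3=0.35, v_4=0.1)
        vs = np.linspace(-1.4, 2.5, 10_000)
        gap = v_nullcline_w(vs, p) - activation_w(vs, p)
        if int(np.sum(np.diff(np.sign(gap)) != 0)) > 1:
            with pytest.raises(ValueError):
                find_fixed_point(p)


class TestHopf:
    def test_eigenvalue_sign_structure(self):
        h = hopf_value(0.0005)
        p = NeuronParams(epsilon=0.0005)
        below = find_fixed_point(p.with_(v_l=h.v_hopf - 0.005))
        above = find_fixed_point(p.with_(v_l=h.v_hopf + 0.005))
        assert below.eigen_real_max < 0 < above.eigen_real_max

    def test_plateau_at_small_epsilon(self):
        vals = [hopf_value(e).v_hopf for e in (1e-6, 5e-6, 1e-5)]
        assert max(vals) - min(vals) <= 1e-3
        for v in vals:
            assert v == pytest.approx(1.524, abs=1e-3)

    def test_monotone_in_epsilon(self):
        # the eigenvalue Hopf value never decreases as eps grows
        vals = [hopf_value(e).v_hopf for e in (1e-6, 1e-5, 1e-4, 1e-3)]
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_no_sign_change_raises(self):
        with pytest.raises(ValueError):
            hopf_value(0.0005, bracket=(1.50, 1.505))

    def test_onset_brackets_excitable_regime(self):
        # v_l = 1.515 must be excitable, 1.525 oscillatory (study setting)
        exc = classify_excitability(NetworkSpec.single_neuron())
        assert exc.classification == "excitable"
        osc = classify_excitability(
            NetworkSpec.single_neuron(params=NeuronParams(v_l=1.525))
        )
        assert osc.classification == "oscillatory"
        assert osc.mean_isi is not None and osc.mean_isi > 0


class TestNetworkFixedPoint:
    def test_matches_isolated_when_uncoupled(self, fixed_point):
        spec = NetworkSpec.motif("C2", SynapseSpec("chemical", 0.0, 0.0, "inhibitory"))
        x = network_fixed_point(spec)
        assert np.allclose(x[:, 0], fixed_point.v_e, atol=1e-9)
        assert np.allclose(x[:, 1], fixed_point.w_e, atol=1e-9)

    def test_steady_state_of_coupled_motif(self):
        from mlsisr.coupling import assemble_drift

        spec = NetworkSpec.motif("C2", SynapseSpec("chemical", 1.5, 10.0, "inhibitory"))
        x = network_fixed_point(spec)
        drift = assemble_drift(spec)
        hist = lambda i, lag: float(x[i, 0])
        assert np.max(np.abs(drift(x, hist, 0.0))) < 1e-9
        # tonic inhibition pulls receiving neurons below the isolated point
        iso = find_fixed_point(spec.layers[0].params)
        assert x[0, 0] < iso.v_e


class TestExcitabilityClassification:
    def test_c7_oscillatory_over_scanned_plane(self):
        for k, t in ((0.125, 5.0), (0.25, 10.0), (0.5, 20.0)):
            spec = NetworkSpec.motif("C7", SynapseSpec("chemical", k, t, "inhibitory"))
            assert classify_excitability(spec).classification == "oscillatory"

    def test_excitatory_chemical_motifs_oscillatory(self):
        for preset in ("C2", "C5"):
            spec = NetworkSpec.motif(
                preset, SynapseSpec("chemical", 0.25, 10.0, "excitatory")
            )
            assert classify_excitability(spec).classification == "oscillatory"

    def test_feedforward_inhibitory_motifs_always_excitable(self):
        for preset in ("C2", "C3", "C4", "C5"):
            spec = NetworkSpec.motif(
                preset, SynapseSpec("chemical", 1.5, 10.0, "inhibitory")
            )
            assert classify_excitability(spec).classification == "excitable"


class TestExcitabilityMap:
    def test_single_neuron_electrical_autapse_map(self):
        def factory(kappa, tau):
            return NetworkSpec.single_neuron(
                autapse=SynapseSpec("electrical", kappa, tau)
            )

        # deterministic limit-cycle periods here are ~1500-2000 time units,
        # so the default horizon (5000) is the minimum that resolves them
        m = excitability_map(
            factory,
            kappa_grid=(0.0, 0.5, 1.0, 1.5),
            tau_grid=(0.0, 7.0, 14.0, 20.0),
        )
        # zero-coupling column reduces to the isolated neuron
        assert (m.classification[0, :] == "excitable").all()
        # both regimes are present over the scanned plane
        assert m.fraction("excitable") > 0 and m.fraction("oscillatory") > 0
        # oscillatory cells carry a positive mean ISI, excitable cells none
        osc = m.classification == "oscillatory"
        assert np.isfinite(m.mean_isi[osc]).all() and (m.mean_isi[osc] > 0).all()
        assert np.isnan(m.mean_isi[~osc]).all()

    def test_map_consistent_with_pointwise_classification(self, rng):
        def factory(kappa, tau):
            return NetworkSpec.motif(
                "C1", SynapseSpec("chemical", kappa, tau, "inhibitory")
            )

        kg, tg = (0.2, 1.2), (2.0, 12.0)
        m = excitability_map(factory, kg, tg, horizon=3000.0)
        for a, b in [(0, 0), (1, 1)]:
            res = classify_excitability(factory(kg[a], tg[b]), horizon=3000.0)
            assert m.classification[a, b] == res.classification
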