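# Named 3-neuron motif adjacency presets, version 1.
#
# Convention: G[i][j] = 1 means neuron i RECEIVES an input from neuron j
# (row = in-edges), matching the summation over presynaptic j in neuron i's
# voltage equation.  Indices are 0-based here; prose about "neuron number
# one" refers to index 0.
#
# Provenance: the source study defines these topologies only in schematic
# figure diagrams that are not reproduced here.  The matrices below are
# reconstructions constrained by every property the accompanying text does
# state, and are verified against those properties by the test suite:
#   * E-presets are symmetric (electrical gap junctions are bidirectional);
#   * C-presets are directed (chemical synapses, single or reciprocal);
#   * in C2 and C3, neuron 0 has the highest in-degree (autapse-enhancement
#     strategy attaches to the highest in-degree neuron);
#   * under strong delayed inhibition (strength 1.5, delay 10) C2 has the
#     poorer spiking coherence of the two (its reported CV minimum is the
#     higher one), which fixes which of the two admissible convergent
#     graphs carries which label;
#   * with inhibitory chemical synapses, C2-C5 stay excitable over the
#     scanned (strength, delay) plane while C7 admits no excitability.
version: 1
presets:
  E1:  # open chain 0-1-2, bidirectional electrical
    - [0, 1, 0]
    - [1, 0, 1]
    - [0, 1, 0]
  E2:  # all-to-all triangle, bidirectional electrical
    - [0, 1, 1]
    - [1, 0, 1]
    - [1, 1, 0]
  C1:  # directed ring 0 -> 1 -> 2 -> 0
    - [0, 0, 1]
    - [1, 0, 0]
    - [0, 1, 0]
  C2:  # convergent fan-in onto neuron 0 plus chain edge 1 -> 2 (in-degrees 2,1,0; acyclic)
    - [0, 1, 1]
    - [0, 0, 0]
    - [0, 1, 0]
  C3:  # convergent fan-in onto neuron 0 (in-degrees 2,0,0; acyclic)
    - [0, 1, 1]
    - [0, 0, 0]
    - [0, 0, 0]
  C4:  # divergent from neuron 0 (acyclic)
    - [0, 0, 0]
    - [1, 0, 0]
    - [1, 0, 0]
  C5:  # feed-forward chain 0 -> 1 -> 2 (acyclic)
    - [0, 0, 0]
    - [1, 0, 0]
    - [0, 1, 0]
  C6:  # reciprocal pair 0 <-> 1 plus edge 0 -> 2
    - [0, 1, 0]
    - [1, 0, 0]
    - [1, 0, 0]
  C7:  # reciprocal chain 0 <-> 1 <-> 2 (no excitable cells with delayed inhibition)
    - [0, 1, 0]
    - [1, 0, 1]
    - [0, 1, 0]
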