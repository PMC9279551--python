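# Methods

## Model

The package simulates the dimensionless, type-II excitable Morris–Lecar
neuron

    dv/dt = f(v, w) + I_coupling + sigma dW/dt
    dw/dt = eps * g(v, w)

    f(v, w) = g_c m_inf(v)(1 - v) + g_l(v_l - v) + g_k w (v_k - v)
    g(v, w) = cosh((v - v_3)/v_4) (w_inf(v) - w)
    m_inf(v) = [1 + tanh((v - v_1)/v_2)]/2,  w_inf(v) = [1 + tanh((v - v_3)/v_4)]/2

with g_c = g_k = 1, g_l = 0.1, v_k = -2, v_1 = 0, v_2 = 0.36, v_3 = -0.2,
v_4 = 0.52.  The leak reversal level `v_l` is the excitability (Hopf)
parameter; `eps << 1` separates the fast voltage from the slow recovery
variable.  All study defaults keep `v_l = 1.515` (below the oscillation
onset) and `eps = 5e-4`.  Gaussian white noise of amplitude `sigma` enters
only the voltage equations, one independent Wiener process per neuron.

Coupling currents (all entering additively in the voltage equation):

* electrical (gap junction, autapse, or multiplex link):
  `kappa (v_src(t - tau) - v_tgt(t))`;
* chemical (directed, sigmoidally gated): `±kappa (v_tgt - v_syn) Gamma(v_src(t - tau))`
  with `Gamma(v) = 1/(1 + exp(-lambda(v - theta_syn)))`, `lambda = 5`,
  `theta_syn = 0`, `v_syn = -1.5`.  Because `v_syn` lies below the
  reachable voltage range, the prefactor is always positive and the sign of
  `kappa` alone decides excitatory (+) versus inhibitory (−); the package
  stores nonnegative strengths with an explicit polarity tag.

For the intra-layer electrical term two index conventions are supported:
the default `conventional` form `v_j(t - tau) - v_i(t)` (consistent with
the autapse and multiplex forms and the wider literature) and an
`as_printed` variant `v_i(t - tau) - v_j(t)` for comparison.

Networks are one or two 3-neuron motif layers; two layers are joined only
between replica neurons (multiplexing).  Motif adjacency presets E1, E2,
C1–C7 ship in `motif_presets.yaml`.  They are reconstructions: the original
topology diagrams were not available to this implementation, so the
matrices were chosen to satisfy every stated constraint — E-presets
symmetric; C2/C3 give neuron 1 the highest in-degree; C2–C5 remain
excitable with inhibitory chemical synapses over the scanned
(strength, delay) plane including (1.5, 10); C7 admits no excitable cell;
electrical motifs and C1 show both regimes — and the test suite asserts
exactly these properties.  Quantities that depend on finer topology details
than these constraints pin down (notably the multiplex-enhancement optima)
should be read with that caveat.

## Integration

The delayed stochastic system is advanced by a two-stage stochastic
Runge–Kutta (Heun/SRA family) step: for additive noise this has strong
order 1.0 and weak order 2.0, and reduces exactly to the deterministic
midpoint RK2 scheme at `sigma = 0`.  Reference step size `dt = 0.008`.
Delayed voltages are read once per step from a ring buffer at the step's
left endpoint and held through both stages; this held-delay treatment is
first-order accurate in the delayed contributions (verified by step-halving
in the tests) and keeps the scheme explicit and reproducible.  Delays are
snapped to the grid when `tau/dt` is within 1e-9 of an integer (true for
every delay used in the study) and linearly interpolated otherwise.
Initial history is constant, equal to the initial condition.  Default
initial condition for stochastic runs is the deterministic network steady
state.

Noise: each neuron draws from its own counter-based Philox stream keyed by
(base seed, realization index, neuron stream id).  This makes runs
bit-for-bit reproducible and makes a neuron embedded in a zero-coupling
network see exactly the noise of the corresponding isolated run — the
reduction property the tests assert.  States are monitored against sanity
bands (v within the physical voltage range widened by 20%, w in
[-0.2, 1.2]); leaving them raises a blow-up error rather than returning
garbage.

The production path is a numba-compiled kernel that detects spikes online
(threshold `v_th = 0`, with a hysteresis re-arm level `v_reset = -0.3`
chosen so the deep relaxation loop always re-arms detection while
threshold chatter cannot double-count; crossing times are linearly
interpolated).  A plain-numpy reference integrator over arbitrary delayed
drift callables provides the independent oracle path used in tests
(Ornstein–Uhlenbeck stationary variance, delayed linear system, kernel
cross-validation).

## Deterministic analysis

Fixed points are located by dense-scan bracketing of the nullcline
intersection plus Brent/Newton polish; stability comes from the analytic
Jacobian of `(f, eps*g)` (closed-form partials, no differencing).  The
Hopf value `v_H(eps)` is bisected to 1e-6 on the sign of the largest
eigenvalue real part.  Excitability of delayed networks is classified by
simulation — steady state plus a suprathreshold kick (+0.3 on every
voltage), horizon 5000 time units, first 20% discarded, oscillatory iff
spiking persists — because delay-induced onsets (saddle-node onto limit
cycle) are not visible to the local Jacobian.  Deterministic limit-cycle
periods in this regime are 500–2000 time units, so the 5000 horizon is the
practical minimum; the excitability-map API exposes it.

`oscillation_onset` bisects the same simulated excitable/oscillatory
boundary over `v_l`.  In this slow–fast regime the simulated onset
(~1.5203 at eps = 5e-4) sits well below the linearized Hopf crossing
(1.5322): the large relaxation cycle becomes attracting before the fixed
point loses linear stability (canard regime).  Both routes are exposed
because each reproduces a different subset of the published anchors (see
below).

## Large-deviation (SISR) theory

Freezing `w` (adiabatic limit) reduces each voltage equation to Brownian
motion in a one-dimensional potential `U(v; w)` with `dU/dv = -drift`.
For coupled networks the same construction applies per neuron with all
coupling inputs frozen at their steady-state values, which makes every
coupling term affine in the neuron's own voltage; setting all strengths to
zero recovers the isolated neuron exactly.  Barriers are
`dU_side = U(v_mid) - U(v_side)` over the three drift zeros
`v_left < v_mid < v_right`, computed by adaptive quadrature of `-drift`
between Brent-refined roots (bracketing grid of 40001 points: near the
fixed point the left well is ~1e-2 wide and a coarse grid misses it).  The
SISR noise window is

    sigma_min = sqrt(2 dU_left(w_e) / ln(1/eps)),
    sigma_max = sqrt(2 F / ln(1/eps)),

with `F` the common barrier height at the recovery value `w*` where the
two barriers are equal.  `F` is implemented as that common height, which
reproduces the published number; the defining condition is sometimes
written as a set of parameter combinations achieving barrier equality, and
the common height is its numerically meaningful scalar reading.

## Reproducibility of the printed anchors

Three published values do not re-derive from the printed equations at
their printed precision; the package computes them faithfully rather than
matching them by construction:

* Onset at eps = 5e-4: printed 1.52010.  The simulated onset converges to
  ~1.5203 (0.01-0.02% away); the eigenvalue Hopf crossing is 1.5322.  The
  printed small-eps plateau (1.524) matches the eigenvalue route to 4e-4.
* `dU_left(w_e)`: printed 1.45e-6.  At the exactly resolved fixed point
  (v_e = -0.576688, w_e = 0.190186) the barrier is 1.7e-10: the fixed
  point lies ~6e-5 in w from the left fold, where the barrier scales as
  (w - w_fold)^{3/2} and a 1e-4 perturbation of v_e changes it by four
  orders of magnitude.  Evaluating at w_inf(-0.5766) = 0.19025 — a fixed
  point resolved to 1e-4 — reproduces 1.449e-6.
* `sigma_min = 6.0e-4` inherits the same ill-conditioning through the
  window formula (the package computes 6.6e-6 at the exact fixed point).
  Dynamically the distinction is immaterial: the barrier rises so steeply
  above w_e that observed spiking onset sits near the printed value, and
  the tested property is that the CV minimum falls inside
  [sigma_min, sigma_max].

`w* = 0.2662`, `F = 0.059274` and `sigma_max = 0.1249` all reproduce to
better than 0.1%.

## Spike statistics

Coherence is the pooled coefficient of variation over the N network
neurons: with per-neuron mean and mean-squared inter-spike intervals
averaged across neurons, `CV = sqrt(<ISI^2> - <ISI>^2)/<ISI>`.  A CV value
is undefined (never coerced) if any neuron yields fewer than two
post-transient spikes.  Per noise amplitude, the CV is averaged over
independent realizations (mean of per-realization CVs, not CV of pooled
intervals); a sigma point is defined only if every realization is.

## Study sizes and scaled-down protocol

The reference protocol is a horizon of 3e5 time units with 6 realizations
per noise amplitude.  Package defaults use the desk-scale protocol chosen
for this implementation: CV–noise curves at horizon 3e4, 3 realizations, 20
log-spaced amplitudes in [1e-4, 0.3]; enhancement maps at horizon 2e4, 2
realizations, 6 amplitudes in [8e-3, 0.12], on coarse 2x3 or 3x3 grids
covering the excitable part of each (strength, delay) plane, with a deterministic
excitability precheck masking oscillatory cells before any stochastic run.
At these sizes a defined CV point rests on ~25-40 intervals per neuron, so
CV estimates carry Monte-Carlo uncertainty of roughly ±0.02-0.05, and all
stochastic comparisons in the tests use tolerances widened accordingly
(±0.05).  The full protocol remains available (`sisr run --full`).

Fig-5-style per-eps CV minima are asserted only as an ordering property
(CV_min strictly increasing in eps over {5e-5, 5e-4, 5e-3}) because the
published per-curve eps values are not printed.

## What the synthetic fixtures do and do not show

The fixtures module generates renewal spike trains with known CV
(periodic, Poisson, gamma), square-pulse voltage traces with known
crossing times (plus sub-threshold noise), exact AR(1) Ornstein–Uhlenbeck
paths, and frozen-w first-passage samples whose log mean escape times are
affine in 1/sigma^2 with slope 2 dU_left (Kramers).  They calibrate each
pipeline stage in isolation; passing them shows the statistics and the
integrator are correct, not that the full model reproduces any particular
biological data.  The Arrhenius property is tested at a frozen w where the
left barrier is ~3e-4 — large enough to dominate the escape prefactor at
the tested noise amplitudes, unlike the barrier at w_e itself.

## Known limitations

* Motif topologies are constraint-based reconstructions (above);
  enhancement-map optima inherit that uncertainty.  In particular the
  heterogeneous-pair chemical multiplexing scan (lower C3, upper C2)
  reaches a best-cell CV minimum around 0.09-0.11 at desk scale — a clear
  enhancement over the motif's isolated ~0.16, but not as deep as the
  strongest published optimum for this strategy; the homogeneous
  electrical scan reproduces its published optimum comfortably.
* The held-delay integrator is first-order in delayed contributions;
  halving dt halves delay-induced bias (tested).  At dt = 0.008 and the
  delays used this bias is far below the Monte-Carlo noise floor.
* Coupled-system potential slices freeze all inputs at steady-state
  values; no claim is made that this adiabatic reading is exact for
  strongly driven neurons.
* Noise is additive and Gaussian only; colored or heavy-tailed noise is
  out of scope.
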