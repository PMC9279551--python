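"""Spike detection, inter-spike intervals and the pooled network CV.

Coherence of noise-induced spiking is quantified by the coefficient of
variation of inter-spike intervals (ISI), pooled over the N neurons of a
network:

    CV = sqrt(<ISI^2>_bar - <ISI>_bar^2) / <ISI>_bar

where <ISI>_bar and <ISI^2>_bar are the across-neuron means of each
neuron's mean ISI and mean squared ISI.  CV -> 0 for periodic spiking,
CV = 1 for a Poisson train, CV > 1 for super-Poissonian irregularity.

Spikes are upward crossings of the threshold v_th = 0.0, with a hysteresis
rule (the trace must first dip below a re-arm level) so that noisy jitter
around the threshold is never double-counted; spike times are linearly
interpolated between straddling samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .integrate import BlowUpError, SimGrid, V_RESET, V_TH, integrate
from .coupling import NetworkSpec

__all__ = [
    "SpikeTrain",
    "ISISample",
    "CVResult",
    "CVCurve",
    "detect_spikes",
    "isi",
    "network_cv",
    "cv_from_spike_times",
    "cv_over_sigma",
]


class InsufficientSpikesError(ValueError):
    """Fewer than 2 spikes: inter-spike intervals are undefined."""


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one neuron with the detection levels used."""

    times: np.ndarray
    v_th: float = V_TH
    v_reset: float = V_RESET

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(t) > 1 and not (np.diff(t) > 0).all():
            raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class ISISample:
    """Per-neuron inter-spike intervals and their first two raw moments."""

    intervals: np.ndarray
    mean: float
    mean_sq: float


def detect_spikes(
    t: np.ndarray,
    v: np.ndarray,
    v_th: float = V_TH,
    v_reset: float = V_RESET,
    t_min: float = 0.0,
) -> SpikeTrain:
    """Detect threshold crossings with hysteresis on a sampled trace.

    A spike is recorded at each upward crossing of ``v_th`` that occurs
    after the trace has visited below ``v_reset`` since the previous spike;
    crossing times are linearly interpolated.  Spikes before ``t_min``
    (transient) are discarded.  An empty train is a valid result.
    """
    if v_reset >= v_th:
        raise ValueError("v_reset must lie below v_th")
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    times: List[float] = []
    armed = v[0] < v_reset
    for k in range(1, len(v)):
        if armed and v[k - 1] <= v_th < v[k]:
            frac = (v_th - v[k - 1]) / (v[k] - v[k - 1])
            ts = t[k - 1] + frac * (t[k] - t[k - 1])
            if ts >= t_min:
                times.append(ts)
            armed = False
        if v[k] < v_reset:
            armed = True
    return SpikeTrain(np.asarray(times), v_th, v_reset)


def isi(train: SpikeTrain) -> ISISample:
    """Successive spike-time differences with first and second raw moments."""
    if len(train) < 2:
        raise InsufficientSpikesError(
            f"need >= 2 spikes for ISIs, got {len(train)}"
        )
    d = np.diff(train.times)
    return ISISample(intervals=d, mean=float(d.mean()), mean_sq=float((d**2).mean()))


@dataclass(frozen=True)
class CVResult:
    """Pooled coefficient of variation over N neurons.

    ``cv`` is None (undefined) iff any neuron contributed fewer than 2
    spikes — neurons are never silently dropped.
    """

    cv: Optional[float]
    n_isi: tuple
    pooled_mean: Optional[float] = None
    pooled_mean_sq: Optional[float] = None

    @property
    def defined(self) -> bool:
        return self.cv is not None


def network_cv(samples: Sequence[Optional[ISISample]]) -> CVResult:
    """Pooled CV of N neurons from their per-neuron ISI samples.

    <ISI>_bar = mean_i <ISI_i>, <ISI^2>_bar = mean_i <ISI_i^2>, and
    CV = sqrt(<ISI^2>_bar - <ISI>_bar^2) / <ISI>_bar.  For N=1 this is the
    ordinary single-neuron CV.  A None entry (neuron with < 2 spikes) makes
    the result undefined.
    """
    n_isi = tuple(0 if s is None else len(s.intervals) for s in samples)
    if any(s is None for s in samples):
        return CVResult(cv=None, n_isi=n_isi)
    m = float(np.mean([s.mean for s in samples]))
    m2 = float(np.mean([s.mean_sq for s in samples]))
    var = m2 - m * m
    cv = math.sqrt(max(var, 0.0)) / m
    return CVResult(cv=cv, n_isi=n_isi, pooled_mean=m, pooled_mean_sq=m2)


def cv_from_spike_times(
    spike_times: Sequence[np.ndarray], t_min: float = 0.0
) -> CVResult:
    """Pooled CV from per-neuron spike-time arrays, dropping times < t_min."""
    samples: List[Optional[ISISample]] = []
    for st in spike_times:
        st = np.asarray(st, dtype=float)
        st = st[st >= t_min]
        if len(st) < 2:
            samples.append(None)
        else:
            samples.append(isi(SpikeTrain(st)))
    return network_cv(samples)


@dataclass
class CVCurve:
    """CV versus noise amplitude, averaged over realizations.

    ``cv_mean[k]`` is the mean over realizations at ``sigma[k]`` (NaN where
    undefined); a sigma point is defined only if every realization produced
    a defined pooled CV.  ``per_realization`` keeps the raw values for
    self-consistency checks and uncertainty estimates.
    """

    sigma: np.ndarray
    cv_mean: np.ndarray
    cv_sd: np.ndarray
    n_defined: np.ndarray
    per_realization: np.ndarray  # (n_sigma, n_realizations), NaN = undefined

    @property
    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.cv_mean)

    @property
    def cv_min(self) -> float:
        m = self.defined_mask
        if not m.any():
            raise ValueError("CV undefined at every sigma point")
        return float(np.nanmin(self.cv_mean[m]))

    @property
    def sigma_at_min(self) -> float:
        m = self.defined_mask
        idx = np.where(m)[0]
        return float(self.sigma[idx[np.argmin(self.cv_mean[idx])]])

    def to_records(self) -> List[dict]:
        return [
            dict(
                sigma=float(s),
                cv_mean=float(c),
                cv_sd=float(sd),
                n_defined=int(n),
            )
            for s, c, sd, n in zip(self.sigma, self.cv_mean, self.cv_sd, self.n_defined)
        ]


def cv_over_sigma(
    spec: NetworkSpec,
    grid: SimGrid,
    sigma_values: Sequence[float],
    neurons: Optional[Sequence[int]] = None,
    initial: Optional[np.ndarray] = None,
) -> CVCurve:
    """CV-versus-noise sweep: per sigma, average the pooled CV over
    ``grid.n_realizations`` independent runs.

    ``neurons`` restricts the pooled CV to a subset (e.g. one layer of a
    multiplex network); default all.  Realizations use split seeds derived
    from (grid.seed, sigma index, realization index), so curves are
    reproducible bit-for-bit and a zero-coupling network run under the same
    seeds equals the single-neuron pipeline exactly.
    """
    sigma_values = np.asarray(list(sigma_values), dtype=float)
    if not (np.diff(sigma_values) > 0).all():
        raise ValueError("sigma_values must be sorted ascending")
    n_sig = len(sigma_values)
    per = np.full((n_sig, grid.n_realizations), np.nan)
    t_cut = grid.transient
    sel = list(neurons) if neurons is not None else None
    for k, sig in enumerate(sigma_values):
        spec_k = spec.with_sigma(float(sig))
        for r in range(grid.n_realizations):
            try:
                traj = integrate(
                    spec_k, grid, initial=initial,
                    realization=k * 10007 + r, record_stride=0,
                )
            except BlowUpError:
                # strong noise can push excursions past the physical
                # voltage band; such points are reported undefined, never
                # as a CV value
                continue
            st = traj.spike_times
            if sel is not None:
                st = [st[i] for i in sel]
            res = cv_from_spike_times(st, t_min=t_cut)
            if res.defined:
                per[k, r] = res.cv
    defined = ~np.isnan(per)
    n_def = defined.sum(axis=1)
    all_def = n_def == grid.n_realizations
    cv_mean = np.full(n_sig, np.nan)
    cv_sd = np.full(n_sig, np.nan)
    if all_def.any():
        cv_mean[all_def] = per[all_def].mean(axis=1)
        cv_sd[all_def] = per[all_def].std(axis=1)
    return CVCurve(
        sigma=sigma_values,
        cv_mean=cv_mean,
        cv_sd=cv_sd,
        n_defined=n_def,
        per_realization=per,
    )
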