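"""Synthetic spike rasters with analytically known metric values.

Each generator is a pure function of its spec and seed, and emits the same
:class:`~granulayer.raster.SpikeRaster` the simulation engine produces, so
the metric and conditioning pipelines can be validated end to end without a
single network simulation:

* ``periodic_raster`` — a population volley at every multiple of the period;
  oracle for the OI = 1 limit (and, with partial participation, for the
  "not every cell joins every cycle" regime of the oscillatory state).
* ``poisson_raster`` — independent homogeneous Poisson trains; null model
  with OI near 0.
* ``drifting_raster`` — each neuron is active in one contiguous burst epoch
  whose start drifts across the population with no reactivation; oracle for
  the passage-of-time regime (SI decays on the burst-lifetime scale).
* ``two_trial_raster`` — a pair of trials identical up to a divergence time
  and independent afterwards; oracle for the reproducibility index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import SpikeRaster

__all__ = [
    "FixtureSpec",
    "periodic_raster",
    "poisson_raster",
    "drifting_raster",
    "two_trial_raster",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic raster.

    ``rate`` is spikes/s (Poisson, drifting bursts); ``period_ms`` the volley
    period (periodic); ``participation`` the fraction of neurons spiking per
    volley; ``lifetime_s`` the burst-epoch length (drifting).
    """

    kind: str
    n_neurons: int = 1024
    duration: float = 2.0
    rate: float = 5.0
    period_ms: float = 111.0
    participation: float = 1.0
    lifetime_s: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1 or self.duration <= 0:
            raise ValueError("need n_neurons >= 1 and duration > 0")
        if not 0.0 <= self.participation <= 1.0:
            raise ValueError("participation must lie in [0, 1]")
        if self.rate < 0 or self.period_ms <= 0 or self.lifetime_s <= 0:
            raise ValueError("rate, period and lifetime must be positive")


def periodic_raster(spec: FixtureSpec) -> SpikeRaster:
    """Volleys at every multiple of the period.

    At ``participation < 1`` a fresh random subset of neurons joins each
    volley, mimicking an oscillation in which not every cell fires on every
    cycle.
    """
    rng = np.random.default_rng(spec.seed)
    period_s = spec.period_ms * 1e-3
    volley_times = np.arange(0.0, spec.duration, period_s)
    ids, times = [], []
    k = max(1, int(round(spec.participation * spec.n_neurons))) \
        if spec.participation > 0 else 0
    for tv in volley_times:
        if k == 0:
            continue
        members = (np.arange(spec.n_neurons) if spec.participation >= 1.0
                   else rng.choice(spec.n_neurons, size=k, replace=False))
        ids.append(members)
        times.append(np.full(members.size, tv))
    if not ids:
        return SpikeRaster(np.empty(0, int), np.empty(0), spec.n_neurons,
                           spec.duration, seed=spec.seed,
                           meta={"fixture": "periodic"})
    return SpikeRaster(np.concatenate(ids), np.concatenate(times),
                       spec.n_neurons, spec.duration, seed=spec.seed,
                       meta={"fixture": "periodic", "period_ms": spec.period_ms,
                             "participation": spec.participation})


def poisson_raster(spec: FixtureSpec) -> SpikeRaster:
    """Independent homogeneous Poisson trains at ``spec.rate`` spikes/s."""
    rng = np.random.default_rng(spec.seed)
    counts = rng.poisson(spec.rate * spec.duration, size=spec.n_neurons)
    ids = np.repeat(np.arange(spec.n_neurons), counts)
    times = rng.uniform(0.0, spec.duration, size=counts.sum())
    return SpikeRaster(ids, times, spec.n_neurons, spec.duration,
                       seed=spec.seed,
                       meta={"fixture": "poisson", "rate": spec.rate})


def drifting_raster(spec: FixtureSpec) -> SpikeRaster:
    """Gradual non-recurrent population turnover.

    Neuron i bursts (Poisson at ``spec.rate`` inside its epoch) during a
    contiguous window of length ``lifetime_s`` whose start is spread evenly
    over the recording; no neuron reactivates.  The expected overlap between
    the active sets at lag tau is ``max(0, 1 - tau/lifetime)``, the
    closed-form oracle for the SI decay.
    """
    if spec.lifetime_s >= spec.duration + 1e-12 and spec.lifetime_s != spec.duration:
        raise ValueError("lifetime must not exceed duration")
    rng = np.random.default_rng(spec.seed)
    span = max(spec.duration - spec.lifetime_s, 0.0)
    starts = np.linspace(0.0, span, spec.n_neurons)
    ids, times = [], []
    for i, s in enumerate(starts):
        n = rng.poisson(spec.rate * spec.lifetime_s)
        if n == 0:
            continue
        ids.append(np.full(n, i))
        times.append(s + rng.uniform(0.0, spec.lifetime_s, size=n))
    if not ids:
        return SpikeRaster(np.empty(0, int), np.empty(0), spec.n_neurons,
                           spec.duration, seed=spec.seed,
                           meta={"fixture": "drifting"})
    times = np.clip(np.concatenate(times), 0.0, np.nextafter(spec.duration, 0.0))
    return SpikeRaster(np.concatenate(ids), times, spec.n_neurons,
                       spec.duration, seed=spec.seed,
                       meta={"fixture": "drifting", "lifetime_s": spec.lifetime_s})


def two_trial_raster(spec: FixtureSpec,
                     divergence_time: float) -> tuple[SpikeRaster, SpikeRaster]:
    """Two Poisson trials identical before ``divergence_time``, independent after."""
    if not 0.0 <= divergence_time <= spec.duration:
        raise ValueError("divergence_time must lie in [0, duration]")
    rng = np.random.default_rng(spec.seed)

    def _poisson_piece(t0: float, t1: float, gen: np.random.Generator):
        counts = gen.poisson(spec.rate * (t1 - t0), size=spec.n_neurons)
        ids = np.repeat(np.arange(spec.n_neurons), counts)
        times = gen.uniform(t0, t1, size=counts.sum())
        return ids, times

    shared_ids, shared_times = _poisson_piece(0.0, divergence_time, rng) \
        if divergence_time > 0 else (np.empty(0, int), np.empty(0))
    trials = []
    for _ in range(2):
        if divergence_time < spec.duration:
            tail_ids, tail_times = _poisson_piece(divergence_time,
                                                  spec.duration, rng)
        else:
            tail_ids, tail_times = np.empty(0, int), np.empty(0)
        trials.append(SpikeRaster(
            np.concatenate([shared_ids, tail_ids]),
            np.concatenate([shared_times, tail_times]),
            spec.n_neurons, spec.duration, seed=spec.seed,
            meta={"fixture": "two_trial", "divergence_s": divergence_time}))
    return trials[0], trials[1]
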