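"""Spike raster container and plain-text I/O.

A :class:`SpikeRaster` is the interchange object between the simulation
engine, the population metrics, and the conditioning readout: a flat list of
(neuron id, spike time) events plus the population metadata needed to
interpret them.  Files are two-column tab-separated text (``neuron_id``,
``time_s``) with ``#``-prefixed JSON metadata on the first line, so rasters
survive as diff-able fixtures and can be produced by any tool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SpikeRaster", "read_raster", "write_raster"]


@dataclass
class SpikeRaster:
    """Spike events for one neural population.

    Parameters
    ----------
    ids : array of int
        Neuron index of each event, in ``[0, n_neurons)``.
    times : array of float
        Event time in seconds, in ``[0, duration)``; sorted ascending.
    n_neurons : int
        Size of the population (silent neurons included).
    duration : float
        Length of the recording in seconds.
    population : str
        Tag such as ``"grc"``, ``"goc"`` or ``"pc"``.
    seed : int or None
        Seed of the process that generated the raster, if any.
    meta : dict
        Free-form provenance (protocol hash, generator parameters, ...).
    """

    ids: np.ndarray
    times: np.ndarray
    n_neurons: int
    duration: float
    population: str = "grc"
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.ids.shape != self.times.shape:
            raise ValueError("ids and times must have equal length")
        if self.ids.size:
            order = np.argsort(self.times, kind="stable")
            self.ids = self.ids[order]
            self.times = self.times[order]
            if self.times[0] < 0 or self.times[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")
            if self.ids.min() < 0 or self.ids.max() >= self.n_neurons:
                raise ValueError("neuron ids must lie in [0, n_neurons)")

    @property
    def n_events(self) -> int:
        return int(self.ids.size)

    def mean_rate(self, t0: float = 0.0, t1: float | None = None) -> float:
        """Population-mean firing rate (spikes/s) over ``[t0, t1)``."""
        if t1 is None:
            t1 = self.duration
        if not t1 > t0:
            raise ValueError("need t1 > t0")
        n = np.count_nonzero((self.times >= t0) & (self.times < t1))
        return n / (self.n_neurons * (t1 - t0))

    def window(self, t0: float, t1: float, *, rezero: bool = False) -> "SpikeRaster":
        """Events with ``t0 <= t < t1``; optionally re-referenced to ``t0``."""
        sel = (self.times >= t0) & (self.times < t1)
        times = self.times[sel] - (t0 if rezero else 0.0)
        dur = (t1 - t0) if rezero else self.duration
        return SpikeRaster(self.ids[sel], times, self.n_neurons, dur,
                           population=self.population, seed=self.seed,
                           meta=dict(self.meta))

    def spike_times(self, neuron: int) -> np.ndarray:
        return self.times[self.ids == neuron]


def write_raster(raster: SpikeRaster, path: str | Path) -> None:
    header = {
        "n_neurons": raster.n_neurons,
        "duration": raster.duration,
        "population": raster.population,
        "seed": raster.seed,
        "meta": raster.meta,
    }
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        for i, t in zip(raster.ids, raster.times):
            fh.write(f"{i}\t{t:.7f}\n")


def read_raster(path: str | Path) -> SpikeRaster:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing JSON metadata header line")
        header = json.loads(first[1:])
        ids, times = [], []
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")
            ids.append(int(a))
            times.append(float(b))
    return SpikeRaster(
        np.array(ids, dtype=np.int64),
        np.array(times, dtype=np.float64),
        n_neurons=int(header["n_neurons"]),
        duration=float(header["duration"]),
        population=header.get("population", "grc"),
        seed=header.get("seed"),
        meta=header.get("meta", {}),
    )
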