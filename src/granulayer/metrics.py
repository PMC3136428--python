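"""Population-activity statistics of the granular layer.

Four statistics quantify the dynamical state of a spiking population:

* **NAC(tau)** — the normalized autocorrelation of the fluctuation
  ``dA(t)`` in the number of neurons active per time bin.  ``NAC(0) = 1``;
  periodic population activity yields periodic NAC.
* **OI** (oscillation index) — the Fourier cosine transform of NAC(tau)
  evaluated at its peak frequency ``f_max``, normalized so a pure-cosine
  NAC scores 1 and a delta-at-zero NAC scores ~0.  OI = 1 means a population
  of active neurons reappears perfectly periodically.
* **SI(tau)** (similarity index) — the average cosine similarity between the
  population vectors of exponentially filtered spike traces (30 ms decay,
  emulating AMPA EPSPs on a Purkinje cell) at times ``t`` and ``t + tau``.
  A monotone decay of SI with |tau| means the active population drifts
  without recurrence — the passage-of-time (POT) code.
* **PI** (POT-representation index) — the height of a Gaussian fit of
  SI(tau) (value at tau = 0 minus the fitted minimum), divided by 0.376,
  the largest height observed anywhere in the [Mg2+] x I_MF plane; PI = 1
  marks the strongest POT representation on that scale.
* **RI(t)** (reproducibility index) — the cosine similarity between the
  trace vectors of two trials at the same time from stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .raster import SpikeRaster

__all__ = [
    "BinnedRaster",
    "AutocorrFunction",
    "EpspTraceMatrix",
    "MetricResult",
    "bin_raster",
    "population_fluctuation",
    "nac",
    "oscillation_index",
    "epsp_traces",
    "similarity_index",
    "si_curve",
    "pot_index",
    "reproducibility_index",
    "compute_metrics",
    "PI_NORMALIZATION",
]

#: Largest Gaussian-fit height of SI(tau) across the whole parameter plane;
#: the denominator that puts PI on a [0, 1] scale.
PI_NORMALIZATION = 0.376


@dataclass
class BinnedRaster:
    """Binary activity matrix s_i(t): neuron i active in bin t."""

    matrix: np.ndarray  # (n_neurons, n_bins) uint8
    bin_ms: float
    window: tuple[float, float]  # seconds

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]


@dataclass
class AutocorrFunction:
    tau_ms: np.ndarray
    nac: np.ndarray
    window_s: float
    bin_ms: float
    degenerate: bool = False  # zero-variance dA (silent or constant activity)


@dataclass
class EpspTraceMatrix:
    """Exponentially filtered spike traces x_i(t), one row per neuron.

    Each spike of neuron i adds a unit jump to x_i, which then decays with
    time constant ``tau_ms`` (default 30 ms, the AMPA EPSP decay on a
    Purkinje cell).  Sampled exactly at the grid times.
    """

    x: np.ndarray  # (n_neurons, n_t)
    t_s: np.ndarray  # grid times, seconds
    tau_ms: float


@dataclass
class MetricResult:
    """All population statistics for one analysis window."""

    window: tuple[float, float]
    bin_ms: float
    oi: float = np.nan
    f_max: float = np.nan
    pi: float = np.nan
    mean_rate: float = np.nan
    nac: AutocorrFunction | None = None
    si_tau_ms: np.ndarray | None = None
    si: np.ndarray | None = None
    gaussian_fit: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "window": list(self.window),
            "bin_ms": self.bin_ms,
            "oi": float(self.oi),
            "f_max": float(self.f_max),
            "pi": float(self.pi),
            "mean_rate": float(self.mean_rate),
            "gaussian_fit": {k: float(v) for k, v in self.gaussian_fit.items()},
            "flags": list(self.flags),
        }


def bin_raster(raster: SpikeRaster, bin_ms: float = 1.0,
               window: tuple[float, float] | None = None) -> BinnedRaster:
    """Binary binning: s_i(t) = 1 iff neuron i spikes at least once in bin t."""
    if window is None:
        window = (0.0, raster.duration)
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("empty analysis window")
    if t0 < 0 or t1 > raster.duration + 1e-12:
        raise ValueError("window must lie within the raster duration")
    n_bins = int(np.floor((t1 - t0) / (bin_ms * 1e-3)))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    sel = (raster.times >= t0) & (raster.times < t0 + n_bins * bin_ms * 1e-3)
    bins = ((raster.times[sel] - t0) / (bin_ms * 1e-3)).astype(np.int64)
    mat = np.zeros((raster.n_neurons, n_bins), dtype=np.uint8)
    mat[raster.ids[sel], bins] = 1
    return BinnedRaster(matrix=mat, bin_ms=bin_ms, window=(t0, t1))


def population_fluctuation(binned: BinnedRaster) -> np.ndarray:
    """dA(t): number of active neurons per bin minus its window mean."""
    counts = binned.matrix.sum(axis=0).astype(np.float64)
    return counts - counts.mean()


def nac(dA: np.ndarray, bin_ms: float = 1.0,
        tau_max_ms: float | None = None) -> AutocorrFunction:
    """Normalized autocorrelation of the population fluctuation.

    ``NAC(tau) = <dA(t) dA(t+tau)>_t / <dA(t)^2>_t`` with the lag average
    taken over the valid (non-wrapping) overlap.  The lag grid runs from 0
    to ``tau_max_ms`` (default ``min(1 s, T/2)``) in one-bin steps.
    """
    dA = np.asarray(dA, dtype=np.float64)
    n = dA.size
    T_s = n * bin_ms * 1e-3
    if tau_max_ms is None:
        tau_max_ms = min(1000.0, T_s * 500.0)  # T/2 in ms
    n_lags = min(n - 1, int(round(tau_max_ms / bin_ms))) + 1
    var = float(np.mean(dA * dA))
    tau = np.arange(n_lags) * bin_ms
    if var <= 0.0:
        return AutocorrFunction(tau_ms=tau, nac=np.full(n_lags, np.nan),
                                window_s=T_s, bin_ms=bin_ms, degenerate=True)
    out = np.empty(n_lags)
    for k in range(n_lags):
        out[k] = np.dot(dA[: n - k], dA[k:]) / (n - k) / var
    return AutocorrFunction(tau_ms=tau, nac=out, window_s=T_s, bin_ms=bin_ms)


def oscillation_index(acf: AutocorrFunction,
                      f_search: tuple[float, float] = (2.0, 100.0),
                      df: float = 0.25,
                      peak_window: float = 0.25) -> tuple[float, float]:
    """(OI, f_max) from the Fourier cosine transform of NAC(tau).

    ``C(f) = sum_tau NAC(tau) cos(2 pi f tau) dtau`` on a frequency grid;
    ``f_max`` is the argmax over the search band (DC excluded by the band's
    lower edge).  OI is then the height of NAC at the recovered period: the
    maximum of NAC(tau) for ``tau`` within ``peak_window`` (fractional) of
    ``1/f_max``, clipped to [0, 1].  A pure-cosine NAC and a periodic
    volley train both score 1; a delta-at-zero (flat-spectrum) NAC scores
    ~0, since NAC vanishes at every positive lag.
    """
    if acf.degenerate:
        raise ValueError("NAC undefined (zero-variance population activity)")
    tau_s = acf.tau_ms * 1e-3
    dtau = acf.bin_ms * 1e-3
    freqs = np.arange(f_search[0], f_search[1] + 0.5 * df, df)
    cosines = np.cos(2.0 * np.pi * freqs[:, None] * tau_s[None, :])
    power = cosines @ acf.nac * dtau
    # a sharply periodic NAC has near-equal power at every harmonic of the
    # fundamental; report the lowest frequency within 5% of the maximum
    near = np.nonzero(power >= 0.95 * power.max())[0]
    i_max = int(near[0]) if power.max() > 0 else int(np.argmax(power))
    f_max = float(freqs[i_max])
    period_ms = 1e3 / f_max
    band = (acf.tau_ms >= (1.0 - peak_window) * period_ms) \
        & (acf.tau_ms <= (1.0 + peak_window) * period_ms)
    if not band.any():  # period beyond the lag grid; fall back to tail lags
        band = acf.tau_ms >= acf.tau_ms[-1] * 0.5
    oi = float(np.clip(np.max(acf.nac[band]), 0.0, 1.0))
    return oi, f_max


def epsp_traces(raster: SpikeRaster, tau_ms: float = 30.0, dt_ms: float = 1.0,
                window: tuple[float, float] | None = None) -> EpspTraceMatrix:
    """Exact exponential spike traces on a regular grid.

    x_i(t_k) = sum over spikes t_s <= t_k of exp(-(t_k - t_s)/tau); computed
    with a per-bin impulse carrying the fractional-offset decay, then a
    recursive exponential filter, so grid samples are exact.
    """
    if window is None:
        window = (0.0, raster.duration)
    t0, t1 = window
    dt_s = dt_ms * 1e-3
    tau_s = tau_ms * 1e-3
    n_t = int(np.floor((t1 - t0) / dt_s)) + 1
    t_grid = t0 + np.arange(n_t) * dt_s
    x = np.zeros((raster.n_neurons, n_t))
    sel = (raster.times >= t0) & (raster.times <= t_grid[-1])
    ids = raster.ids[sel]
    ts = raster.times[sel]
    # first grid point at or after each spike, with the partial-bin decay
    k0 = np.ceil((ts - t0) / dt_s - 1e-12).astype(np.int64)
    amp = np.exp(-(t_grid[k0] - ts) / tau_s)
    np.add.at(x, (ids, k0), amp)
    decay = np.exp(-dt_s / tau_s)
    for k in range(1, n_t):
        x[:, k] += x[:, k - 1] * decay
    return EpspTraceMatrix(x=x, t_s=t_grid, tau_ms=tau_ms)


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return np.nan
    return float(np.dot(u, v) / (nu * nv))


def similarity_index(traces: EpspTraceMatrix, t_s: float, tau_s: float) -> float:
    """SI between the population vectors at times t and t + tau.

    Normalized inner product; NaN (flagged by callers) if either population
    vector is zero.
    """
    k1 = int(round((t_s - traces.t_s[0]) / (traces.t_s[1] - traces.t_s[0])))
    k2 = int(round((t_s + tau_s - traces.t_s[0]) / (traces.t_s[1] - traces.t_s[0])))
    if not (0 <= k1 < traces.x.shape[1] and 0 <= k2 < traces.x.shape[1]):
        raise ValueError("t and t + tau must lie inside the trace window")
    return _cosine(traces.x[:, k1], traces.x[:, k2])


def si_curve(traces: EpspTraceMatrix,
             tau_max_ms: float | None = None) -> tuple[np.ndarray, np.ndarray, dict]:
    """SI(tau) averaged over t at fixed tau, lag pairs inside the window.

    Returns (tau_ms grid, SI values, qc dict).  Time points with a zero
    population vector are excluded from the averages and counted in the QC
    report.
    """
    x = traces.x
    n_t = x.shape[1]
    dt_ms = (traces.t_s[1] - traces.t_s[0]) * 1e3
    T_ms = n_t * dt_ms
    if tau_max_ms is None:
        tau_max_ms = min(1000.0, T_ms / 2.0)
    n_lags = min(n_t - 1, int(round(tau_max_ms / dt_ms))) + 1
    norms = np.linalg.norm(x, axis=0)
    valid = norms > 0.0
    xn = np.where(valid[None, :], x / np.where(valid, norms, 1.0)[None, :], 0.0)
    gram = xn.T @ xn
    tau = np.arange(n_lags) * dt_ms
    si = np.empty(n_lags)
    for k in range(n_lags):
        pair_ok = valid[: n_t - k] & valid[k:]
        if not pair_ok.any():
            si[k] = np.nan
            continue
        si[k] = np.mean(np.diagonal(gram, offset=k)[pair_ok])
    qc = {"n_silent_bins": int(np.count_nonzero(~valid)), "n_bins": n_t}
    return tau, si, qc


def pot_index(tau_ms: np.ndarray, si: np.ndarray,
              normalization: float = PI_NORMALIZATION) -> tuple[float, dict]:
    """POT-representation index from a Gaussian fit of SI(tau).

    Fits ``SI(tau) ~ (a - b) exp(-tau^2 / (2 sigma^2)) + b`` by unweighted
    least squares, takes the height from the fitted value at tau = 0 down to
    the minimum of the fitted curve on the lag grid, and divides by the
    ``normalization`` constant (0.376).  Clipped to [0, 1].
    """
    ok = np.isfinite(si)
    tau = np.asarray(tau_ms, dtype=float)[ok]
    y = np.asarray(si, dtype=float)[ok]
    if y.size < 4:
        return np.nan, {"error": "too few SI samples"}
    if np.ptp(y) < 1e-12:
        return 0.0, {"amplitude": 0.0, "baseline": float(y[0]), "sigma_ms": np.inf}

    def gauss(t, a, b, sigma):
        return (a - b) * np.exp(-(t * t) / (2.0 * sigma * sigma)) + b

    a0 = float(y[0])
    b0 = float(y.min())
    # half width at half height as the sigma seed
    half = b0 + 0.5 * (a0 - b0)
    below = np.nonzero(y <= half)[0]
    s0 = float(tau[below[0]]) if below.size else float(tau[-1] / 2.0)
    s0 = max(s0, tau[1] if tau.size > 1 else 1.0)
    try:
        popt, _ = curve_fit(gauss, tau, y, p0=(a0, b0, s0),
                            bounds=([-2.0, -2.0, 1e-3], [2.0, 2.0, np.inf]),
                            maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return np.nan, {"error": f"fit failure: {exc}"}
    a, b, sigma = (float(v) for v in popt)
    fitted = gauss(tau, a, b, sigma)
    height = float(fitted[0] - fitted.min())
    pi = float(np.clip(height / normalization, 0.0, 1.0))
    return pi, {"amplitude": a, "baseline": b, "sigma_ms": sigma, "height": height}


def reproducibility_index(traces1: EpspTraceMatrix,
                          traces2: EpspTraceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """RI(t): cosine similarity between two trials' trace vectors at each t.

    Both trace matrices must be aligned to their stimulus onsets and share
    the time grid.  Returns (t_s, RI); entries where either trial has a zero
    population vector are NaN.
    """
    if traces1.x.shape != traces2.x.shape:
        raise ValueError("trials must share neuron count and time grid")
    n1 = np.linalg.norm(traces1.x, axis=0)
    n2 = np.linalg.norm(traces2.x, axis=0)
    dot = np.einsum("ij,ij->j", traces1.x, traces2.x)
    with np.errstate(invalid="ignore", divide="ignore"):
        ri = dot / (n1 * n2)
    ri[(n1 == 0) | (n2 == 0)] = np.nan
    return traces1.t_s - traces1.t_s[0], ri


def compute_metrics(raster: SpikeRaster, window: tuple[float, float],
                    bin_ms: float = 1.0, trace_tau_ms: float = 30.0,
                    f_search: tuple[float, float] = (2.0, 100.0)) -> MetricResult:
    """One-call OI / f_max / PI / rate summary for an analysis window."""
    res = MetricResult(window=window, bin_ms=bin_ms)
    res.mean_rate = raster.mean_rate(*window)
    binned = bin_raster(raster, bin_ms=bin_ms, window=window)
    dA = population_fluctuation(binned)
    acf = nac(dA, bin_ms=bin_ms)
    res.nac = acf
    if acf.degenerate:
        res.flags.append("silent-or-constant population: OI undefined")
    else:
        res.oi, res.f_max = oscillation_index(acf, f_search=f_search)
    traces = epsp_traces(raster, tau_ms=trace_tau_ms, dt_ms=bin_ms, window=window)
    tau, si, qc = si_curve(traces)
    res.si_tau_ms, res.si = tau, si
    if qc["n_silent_bins"]:
        res.flags.append(f"{qc['n_silent_bins']}/{qc['n_bins']} silent bins "
                         "excluded from SI averages")
    pi, fit = pot_index(tau, si)
    res.pi = pi
    res.gaussian_fit = fit
    if "error" in fit:
        res.flags.append(f"PI fit: {fit['error']}")
    return res
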