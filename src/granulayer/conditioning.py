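"""Delay eyelid-conditioning readout: PF->PC depression and the learned pause.

A granule raster recorded during a conditioned-stimulus (CS) epoch drives a
spiking Purkinje cell (PC) through parallel-fiber AMPA synapses modeled as
30 ms-decay exponential traces.  Conditioning is a one-shot, binary
long-term depression rule: any granule cluster that fires within a brief
window (default 0.05-0.1 s) before the unconditioned-stimulus (US) onset
has its PF->PC weight set from 1 to 0.  Because the active population
drifts without recurrence during the CS (the passage-of-time code), zeroing
exactly the clusters active just before the US carves a well-timed pause
into the PC's firing — the neural correlate of the conditioned eyeblink.
The US itself only gates the plasticity; it contributes no current to the
PC dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .cells import LOCKOUT_MS, build_gate_tables, pack_soma
from .metrics import epsp_traces
from .params import SomaParams
from .raster import SpikeRaster

__all__ = [
    "PcParams",
    "WeightVector",
    "LTD_WINDOWS",
    "apply_ltd",
    "run_pc",
    "max_firing_rate",
    "calibrate_pc",
    "run_conditioned_pc",
    "no_cs_control",
]

#: LTD coincidence-window presets (seconds before US onset), named after the
#: eyeblink-conditioning literatures they summarize.
LTD_WINDOWS = {
    "default": (0.05, 0.1),
    "chen_thompson": (0.0, 0.2),
    "wang": (0.1, 0.15),
}


def _default_pc_soma() -> SomaParams:
    return SomaParams(
        capacitance_pF=100.0,
        g_leak_nS=10.0,
        e_leak_mV=-65.0,
        g_na_nS=7000.0,
        e_na_mV=50.0,
        g_kdr_nS=2300.0,
        e_k_mV=-90.0,
        # the AHP grades the f-I curve so partial PF drive yields partial
        # rates rather than all-or-none firing
        ahp_increment_nS=25.0,
        ahp_tau_ms=20.0,
        v_shift_mV=5.0,  # keeps the rest state stable without drive
    )


@dataclass(frozen=True)
class PcParams:
    """Simple spiking Purkinje cell: one Hodgkin–Huxley-style soma.

    PF drive enters as a conductance ``pf_peak_nS * sum_i w_i x_i(t)`` with
    reversal ``pf_reversal_mV``, where x_i are the 30 ms-decay spike traces.
    ``pf_peak_nS`` is calibrated so the CS-driven maximum rate is
    100 spikes/s with all weights at 1.  Integrated with first-order
    explicit Euler at a 20 us step.
    """

    soma: SomaParams = field(default_factory=_default_pc_soma)
    pf_peak_nS: float = 0.04
    pf_reversal_mV: float = 0.0
    trace_tau_ms: float = 30.0
    dt_us: float = 20.0
    integrator: str = "euler"


@dataclass
class WeightVector:
    """Binary PF->PC weights after (or before) conditioning."""

    w: np.ndarray  # {0,1} per granule cluster
    isi_s: float | None = None
    ltd_window_s: tuple[float, float] = LTD_WINDOWS["default"]
    cs_onset_s: float = 0.0

    @property
    def n_depressed(self) -> int:
        return int(np.count_nonzero(self.w == 0))


def apply_ltd(grc_raster: SpikeRaster, cs_onset: float, isi: float,
              window: tuple[float, float] = LTD_WINDOWS["default"],
              weights: WeightVector | None = None) -> WeightVector:
    """Zero the weight of every grc spiking in the pre-US coincidence window.

    The US arrives at ``cs_onset + isi``; a weight w_i drops to 0 iff neuron
    i has at least one spike in ``[US - window[1], US - window[0]]``.
    Idempotent: applying twice equals applying once.
    """
    us = cs_onset + isi
    lo, hi = us - window[1], us - window[0]
    if lo < 0 or hi > grc_raster.duration:
        raise ValueError("LTD window falls outside the raster")
    w = (np.ones(grc_raster.n_neurons) if weights is None
         else weights.w.copy())
    sel = (grc_raster.times >= lo) & (grc_raster.times <= hi)
    w[np.unique(grc_raster.ids[sel])] = 0.0
    return WeightVector(w=w, isi_s=isi, ltd_window_s=window,
                        cs_onset_s=cs_onset)


def run_pc(pc: PcParams, grc_raster: SpikeRaster,
           weights: np.ndarray | WeightVector | None = None,
           record_v: bool = False,
           ) -> SpikeRaster | tuple[SpikeRaster, np.ndarray, np.ndarray]:
    """Drive the PC with the weighted PF trace sum over the whole raster."""
    if weights is None:
        w = np.ones(grc_raster.n_neurons)
    elif isinstance(weights, WeightVector):
        w = weights.w
    else:
        w = np.asarray(weights, dtype=float)
    traces = epsp_traces(grc_raster, tau_ms=pc.trace_tau_ms, dt_ms=1.0)
    drive = w @ traces.x  # total trace sum on the 1 ms grid

    dt_ms = pc.dt_us * 1e-3
    n_steps = int(round(grc_raster.duration * 1e3 / dt_ms))
    # step-hold the 1 ms drive onto the integration grid
    grid_idx = np.minimum((np.arange(n_steps) * dt_ms).astype(np.int64),
                          drive.size - 1)
    g_exc = pc.pf_peak_nS * drive[grid_idx]
    tabs = build_gate_tables(dt_ms)
    par = pack_soma(pc.soma, dt_ms)
    sp_step = np.zeros(int(grc_raster.duration * 600) + 16, np.int64)
    v_trace = np.zeros(n_steps if record_v else 1)
    integrator = {"cn": 0, "exp_euler": 1, "euler": 2}[pc.integrator]
    status, at, count = _kernels.run_single_soma(
        dt_ms, n_steps, integrator, int(round(LOCKOUT_MS / dt_ms)),
        tabs.v0, tabs.inv_dv, tabs.minf, tabs.mfac, tabs.hinf, tabs.hfac,
        tabs.ninf, tabs.nfac,
        par, np.zeros(n_steps), g_exc, pc.pf_reversal_mV,
        pc.soma.e_leak_mV, sp_step, record_v, v_trace)
    if status == _kernels.ERR_NONFINITE:
        raise FloatingPointError(f"PC integration failure at step {at}")
    if status == _kernels.ERR_SPIKE_OVERFLOW:
        raise RuntimeError(f"PC spike buffer overflow at step {at}")
    raster = SpikeRaster(np.zeros(count, np.int64),
                         sp_step[:count] * dt_ms * 1e-3, 1,
                         grc_raster.duration, population="pc",
                         meta={"pf_peak_nS": pc.pf_peak_nS})
    if record_v:
        t_axis = np.arange(n_steps) * dt_ms * 1e-3
        return raster, t_axis, v_trace
    return raster


def max_firing_rate(raster: SpikeRaster, window_s: float = 0.1) -> float:
    """Maximum rate (spikes/s) over a sliding window of length ``window_s``."""
    t = np.sort(raster.times)
    if t.size == 0:
        return 0.0
    j = np.searchsorted(t, t + window_s, side="left")
    return float(np.max(j - np.arange(t.size)) / window_s)


def calibrate_pc(pc: PcParams, grc_raster_cs: SpikeRaster,
                 target_rate: float = 100.0, tol: float = 2.0,
                 g_lo: float = 1e-4, g_hi: float = 1.0,
                 max_iter: int = 60) -> PcParams:
    """Bisect the PF peak conductance to the CS-driven maximum-rate target.

    The maximum rate (100 ms sliding window, all weights 1) is monotone in
    the peak conductance; bisection runs until it lands within ``tol``
    spikes/s of ``target_rate``.
    """

    def rate_at(g: float) -> float:
        return max_firing_rate(run_pc(replace(pc, pf_peak_nS=g),
                                      grc_raster_cs))

    r_lo, r_hi = rate_at(g_lo), rate_at(g_hi)
    if not (r_lo < target_rate < r_hi):
        raise ValueError(
            f"calibration range does not bracket {target_rate} spikes/s "
            f"(rates {r_lo:.1f}..{r_hi:.1f})")
    for _ in range(max_iter):
        g_mid = np.sqrt(g_lo * g_hi)  # geometric: conductance spans decades
        r_mid = rate_at(g_mid)
        if abs(r_mid - target_rate) <= tol:
            return replace(pc, pf_peak_nS=float(g_mid))
        if r_mid < target_rate:
            g_lo = g_mid
        else:
            g_hi = g_mid
    raise RuntimeError("PC calibration did not converge")


def run_conditioned_pc(pc: PcParams, weights: WeightVector,
                       grc_raster: SpikeRaster, record_v: bool = False):
    """PC response after conditioning, with the learned pause endpoints.

    The pause is the longest PC interspike interval intersecting
    ``[US - 0.3 s, US + 0.3 s]``; returns ``(pc_raster, (t_stop,
    t_restart))`` in raster time.  Flags (raises) if the PC never spikes.
    """
    out = run_pc(pc, grc_raster, weights, record_v=record_v)
    pc_raster = out[0] if record_v else out
    if pc_raster.n_events == 0:
        raise ValueError("PC elicited no spikes; pause undefined")
    us = weights.cs_onset_s + (weights.isi_s or 0.0)
    t = np.sort(pc_raster.times)
    edges = np.concatenate(([0.0], t, [grc_raster.duration]))
    best = None
    for a, b in zip(edges[:-1], edges[1:]):
        if b < us - 0.3 or a > us + 0.3:
            continue
        if best is None or (b - a) > (best[1] - best[0]):
            best = (a, b)
    pause = (float(best[0]), float(best[1])) if best else (np.nan, np.nan)
    if record_v:
        return pc_raster, pause, out[1], out[2]
    return pc_raster, pause


def no_cs_control(pc: PcParams, small_current_raster: SpikeRaster,
                  ) -> tuple[SpikeRaster, float]:
    """PC driven by the oscillatory (small-current) granular-layer state.

    Returns the PC raster and its burst frequency (Hz), which tracks the
    granular-layer oscillation (~9 Hz at the default parameters).
    """
    pc_raster = run_pc(pc, small_current_raster)
    if pc_raster.n_events < 4:
        return pc_raster, np.nan
    # group spikes into bursts (new burst after a >50 ms gap) and report the
    # burst rate, which tracks the population cycle rather than the
    # intra-burst firing
    t = np.sort(pc_raster.times)
    n_bursts = 1 + int(np.count_nonzero(np.diff(t) > 0.05))
    return pc_raster, n_bursts / pc_raster.duration
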