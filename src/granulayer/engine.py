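"""Network integration under a stimulus protocol.

``run_protocol`` advances the whole sheet (granule clusters + two-compartment
Golgi cells) with a fixed 20 us step and emits spike rasters for both
populations.  Mossy-fiber drive is a piecewise-constant current injected
into every granule soma (the default protocol is 10.7 pA for 2 s, 22.7 pA
for 2 s, 10.7 pA for 2 s); Golgi cells receive no direct drive unless a
``goc_current_ratio`` is set.  Everything is deterministic given the graph,
the parameter set and the seed (which only draws the per-cell Golgi leak
reversals).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .cells import LOCKOUT_MS, build_gate_tables, pack_soma
from .network import NetworkGraph, build_all_to_all
from .params import ModelParams
from .raster import SpikeRaster

__all__ = [
    "StimulusProtocol",
    "SimResult",
    "default_protocol",
    "repeat_protocol",
    "constant_protocol",
    "run_protocol",
    "run_repeat_protocol",
    "ablate",
]

SMALL_CURRENT_PA = 10.7
LARGE_CURRENT_PA = 22.7


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant mossy-fiber current schedule.

    ``segments`` are contiguous ``(t_start_s, t_end_s, i_pA)`` tuples applied
    to all granule cells; ``goc_current_ratio`` scales the same schedule
    into a direct Golgi somatic current (0 = mossy input to Golgi cells
    omitted, the default).  No noise is added to the currents.
    """

    segments: tuple[tuple[float, float, float], ...]
    mg_mM: float = 1.2
    goc_current_ratio: float = 0.0

    def __post_init__(self) -> None:
        prev_end = 0.0
        for t0, t1, i in self.segments:
            if not np.isfinite(i):
                raise ValueError("currents must be finite")
            if abs(t0 - prev_end) > 1e-9 or t1 <= t0:
                raise ValueError("segments must be contiguous and ordered")
            prev_end = t1
        if self.mg_mM < 0:
            raise ValueError("Mg2+ concentration must be >= 0")

    @property
    def duration(self) -> float:
        return self.segments[-1][1]

    def current_steps(self, dt_ms: float) -> np.ndarray:
        """Per-step grc current array at resolution ``dt_ms``."""
        n = int(round(self.duration * 1e3 / dt_ms))
        out = np.empty(n)
        for t0, t1, i in self.segments:
            k0 = int(round(t0 * 1e3 / dt_ms))
            k1 = min(int(round(t1 * 1e3 / dt_ms)), n)
            out[k0:k1] = i
        return out

    def hash(self) -> str:
        key = json.dumps([list(map(float, s)) for s in self.segments]
                         + [self.mg_mM, self.goc_current_ratio])
        return hashlib.sha256(key.encode()).hexdigest()[:12]


def default_protocol(mg_mM: float = 1.2,
                     goc_current_ratio: float = 0.0,
                     small_pA: float = SMALL_CURRENT_PA,
                     large_pA: float = LARGE_CURRENT_PA,
                     duration_s: float = 6.0) -> StimulusProtocol:
    """Small (2 s) -> large (2 s) -> small current; truncated to ``duration_s``."""
    segs = [(0.0, 2.0, small_pA), (2.0, 4.0, large_pA), (4.0, 6.0, small_pA)]
    out = []
    for t0, t1, i in segs:
        if t0 >= duration_s:
            break
        out.append((t0, min(t1, duration_s), i))
    return StimulusProtocol(tuple(out), mg_mM=mg_mM,
                            goc_current_ratio=goc_current_ratio)


def repeat_protocol(mg_mM: float = 1.2,
                    small_pA: float = SMALL_CURRENT_PA,
                    large_pA: float = LARGE_CURRENT_PA) -> StimulusProtocol:
    """Two large-current epochs (2-4 s and 6-8 s) in one continuous run."""
    return StimulusProtocol((
        (0.0, 2.0, small_pA), (2.0, 4.0, large_pA),
        (4.0, 6.0, small_pA), (6.0, 8.0, large_pA),
    ), mg_mM=mg_mM)


def constant_protocol(i_pA: float, duration_s: float = 2.0,
                      mg_mM: float = 1.2,
                      goc_current_ratio: float = 0.0) -> StimulusProtocol:
    return StimulusProtocol(((0.0, duration_s, i_pA),), mg_mM=mg_mM,
                            goc_current_ratio=goc_current_ratio)


@dataclass
class SimResult:
    grc: SpikeRaster
    goc: SpikeRaster
    protocol: StimulusProtocol
    traces: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def run_protocol(graph: NetworkGraph, params: ModelParams,
                 protocol: StimulusProtocol, dt_us: float = 20.0,
                 seed: int = 0, integrator: str = "cn",
                 record_v: tuple[list[int], list[int]] | None = None,
                 trace_decim_ms: float = 1.0) -> SimResult:
    """Integrate the network for the whole protocol.

    ``record_v`` optionally lists (grc indices, goc indices) whose membrane
    potentials are recorded, decimated to ``trace_decim_ms``.  The result is
    deterministic given ``(graph, params, protocol, dt_us, integrator,
    seed)``; the seed draws only the Golgi leak reversals.
    """
    if integrator not in ("cn", "exp_euler"):
        raise ValueError(f"unknown integrator {integrator!r}")
    t_wall = time.perf_counter()
    dt_ms = dt_us * 1e-3
    n_steps = int(round(protocol.duration * 1e3 / dt_ms))
    tabs = build_gate_tables(dt_ms)
    n_grc, n_goc = graph.n_grc, graph.n_goc

    rng = np.random.default_rng(seed)
    lo, hi = params.goc.e_leak_range_mV
    goc_eleak = rng.uniform(lo, hi, size=n_goc)

    gp = pack_soma(params.grc.soma, dt_ms)
    gs = params.goc.soma
    op = np.array([
        gs.capacitance_pF, gs.g_leak_nS, gs.g_na_nS, gs.e_na_mV,
        gs.g_kdr_nS, gs.e_k_mV, gs.ahp_increment_nS,
        np.exp(-dt_ms / gs.ahp_tau_ms),
        params.goc.dend_capacitance_pF, params.goc.dend_g_leak_nS,
        params.goc.axial_g_nS, gs.v_shift_mV,
    ])

    gaba = params.grc.gaba
    ampa = params.goc.ampa
    nmda = params.goc.nmda
    mg = replace(params.mg_block, mg_mM=protocol.mg_mM)

    i_grc = protocol.current_steps(dt_ms)
    i_goc = i_grc * protocol.goc_current_ratio

    # state
    Vg = np.full(n_grc, params.grc.soma.e_leak_mV)
    m0, h0, n0 = tabs.steady_state(params.grc.soma.e_leak_mV
                                   - params.grc.soma.v_shift_mV)
    mg_arr = np.full(n_grc, m0)
    hg = np.full(n_grc, h0)
    ng_arr = np.full(n_grc, n0)
    ahpg = np.zeros(n_grc)
    gaba_r = np.zeros(n_grc)
    gaba_d = np.zeros(n_grc)
    Vs = goc_eleak.copy()
    Vd = goc_eleak.copy()
    mo = np.empty(n_goc)
    ho = np.empty(n_goc)
    no = np.empty(n_goc)
    for j in range(n_goc):
        mo[j], ho[j], no[j] = tabs.steady_state(goc_eleak[j]
                                                - gs.v_shift_mV)
    ahpo = np.zeros(n_goc)
    ampa_r = np.zeros(n_goc)
    ampa_d = np.zeros(n_goc)
    nmda_r = np.zeros(n_goc)
    nmda_d = np.zeros(n_goc)

    pf_indptr, pf_targets = graph.csr_out("pf")
    inh_indptr, inh_targets = graph.csr_out("inh")

    # Under the cluster interpretation each unit aggregates ~1,000 real
    # cells, so the total synaptic conductance a target receives is fixed
    # and divided among its presynaptic partners.
    def _scale(deg: np.ndarray, alpha: float) -> np.ndarray:
        if alpha == 0.0:
            return np.ones(deg.size)
        interior = deg[deg > 0]
        mean_deg = interior.mean() if interior.size else 1.0
        out = np.zeros(deg.size)
        out[deg > 0] = (mean_deg / deg[deg > 0]) ** alpha
        return out

    gaba_scale = _scale(graph.inh_in_degrees(), params.normalize_inhibition)
    exc_scale = _scale(graph.pf_in_degrees(), params.normalize_excitation)

    cap_g = int(n_grc * protocol.duration * 400) + 1024
    cap_o = int(n_goc * protocol.duration * 400) + 1024
    grc_sp_step = np.zeros(cap_g, np.int64)
    grc_sp_id = np.zeros(cap_g, np.int64)
    goc_sp_step = np.zeros(cap_o, np.int64)
    goc_sp_id = np.zeros(cap_o, np.int64)

    if record_v is not None:
        rec_grc = np.asarray(record_v[0], np.int64)
        rec_goc = np.asarray(record_v[1], np.int64)
        rec_every = max(1, int(round(trace_decim_ms / dt_ms)))
        n_samp = (n_steps + rec_every - 1) // rec_every
    else:
        rec_grc = np.empty(0, np.int64)
        rec_goc = np.empty(0, np.int64)
        rec_every = 0
        n_samp = 1
    tr_vg = np.zeros((rec_grc.size, n_samp))
    tr_vs = np.zeros((rec_goc.size, n_samp))
    tr_vd = np.zeros((rec_goc.size, n_samp))

    status, at_step, n_sp_g, n_sp_o = _kernels.run_granular_network(
        dt_ms, n_steps, {"cn": 0, "exp_euler": 1}[integrator],
        int(round(LOCKOUT_MS / dt_ms)),
        tabs.v0, tabs.inv_dv, tabs.minf, tabs.mfac, tabs.hinf, tabs.hfac,
        tabs.ninf, tabs.nfac,
        gp,
        np.exp(-dt_ms / gaba.tau_rise), np.exp(-dt_ms / gaba.tau_decay),
        gaba.peak_conductance * gaba.norm, gaba.reversal,
        op, goc_eleak,
        np.exp(-dt_ms / ampa.tau_rise), np.exp(-dt_ms / ampa.tau_decay),
        ampa.peak_conductance * ampa.norm, ampa.reversal,
        np.exp(-dt_ms / nmda.tau_rise), np.exp(-dt_ms / nmda.tau_decay),
        nmda.peak_conductance * nmda.norm, nmda.reversal,
        mg.mg_mM / mg.k0_mM, 1.0 / mg.vs_mV,
        gaba_scale, exc_scale,
        i_grc, i_goc,
        pf_indptr, pf_targets, inh_indptr, inh_targets,
        Vg, mg_arr, hg, ng_arr, ahpg, gaba_r, gaba_d,
        Vs, Vd, mo, ho, no, ahpo, ampa_r, ampa_d, nmda_r, nmda_d,
        grc_sp_step, grc_sp_id, goc_sp_step, goc_sp_id,
        rec_grc, rec_goc, rec_every, tr_vg, tr_vs, tr_vd,
    )
    if status == _kernels.ERR_NONFINITE:
        raise FloatingPointError(
            f"integration failure: non-finite state at step {at_step} "
            f"(t = {at_step * dt_ms:.3f} ms)")
    if status == _kernels.ERR_SPIKE_OVERFLOW:
        raise RuntimeError(f"spike buffer overflow at step {at_step}")

    meta = {
        "dt_us": dt_us,
        "integrator": integrator,
        "seed": seed,
        "protocol_hash": protocol.hash(),
        "mg_mM": protocol.mg_mM,
        "wall_s": time.perf_counter() - t_wall,
    }
    grc_raster = SpikeRaster(
        grc_sp_id[:n_sp_g], grc_sp_step[:n_sp_g] * dt_ms * 1e-3,
        n_grc, protocol.duration, population="grc", seed=seed, meta=dict(meta))
    goc_raster = SpikeRaster(
        goc_sp_id[:n_sp_o], goc_sp_step[:n_sp_o] * dt_ms * 1e-3,
        n_goc, protocol.duration, population="goc", seed=seed, meta=dict(meta))
    traces = {}
    if record_v is not None:
        t_axis = np.arange(n_samp) * rec_every * dt_ms * 1e-3
        traces = {"t_s": t_axis, "grc_v": tr_vg, "goc_v_soma": tr_vs,
                  "goc_v_dend": tr_vd}
    return SimResult(grc=grc_raster, goc=goc_raster, protocol=protocol,
                     traces=traces, meta=meta)


def run_repeat_protocol(graph: NetworkGraph, params: ModelParams,
                        seed: int = 0, mg_mM: float = 1.2,
                        dt_us: float = 20.0,
                        ) -> tuple[SimResult, SpikeRaster, SpikeRaster]:
    """One continuous run with two large-current epochs (2-4 s, 6-8 s).

    Returns the full result plus the two epochs re-referenced to their
    onsets, ready for the reproducibility index.
    """
    protocol = repeat_protocol(mg_mM=mg_mM)
    result = run_protocol(graph, params, protocol, dt_us=dt_us, seed=seed)
    epoch1 = result.grc.window(2.0, 4.0, rezero=True)
    epoch2 = result.grc.window(6.0, 8.0, rezero=True)
    return result, epoch1, epoch2


def ablate(graph: NetworkGraph | None, params: ModelParams | None,
           which: str):
    """Return modified copies with the named mechanism removed.

    ``goc_to_grc_inhibition`` empties the inhibitory edge list;
    ``nmda`` zeroes the NMDA peak conductance (the [Mg2+] -> infinity
    limit of the block); ``all_to_all`` replaces the graph with the full
    candidate connectivity.  Originals are untouched.
    """
    if which == "goc_to_grc_inhibition":
        if graph is None:
            raise ValueError("this ablation needs a graph")
        out = NetworkGraph(
            geometry=graph.geometry,
            pf_src=graph.pf_src.copy(), pf_dst=graph.pf_dst.copy(),
            inh_src=np.empty(0, np.int64), inh_dst=np.empty(0, np.int64),
            p=graph.p, seed=graph.seed,
            build_stats=dict(graph.build_stats))
        return out
    if which == "nmda":
        if params is None:
            raise ValueError("this ablation needs params")
        return replace(params, goc=replace(
            params.goc, nmda=replace(params.goc.nmda, peak_conductance=0.0)))
    if which == "all_to_all":
        if graph is None:
            raise ValueError("this ablation needs a graph")
        return build_all_to_all(graph.geometry)
    raise ValueError(f"unknown ablation {which!r}")
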