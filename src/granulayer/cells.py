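"""Single-cell models: gate kinetics, tables, and per-step update units.

The spiking compartments share one surrogate kinetic scheme — Traub–Miles
transient Na (m^3 h) and delayed-rectifier K (n^4) gates — evaluated through
steady-state / decay-factor lookup tables, plus a spike-triggered AHP
conductance.  :class:`GrcUnit` and :class:`GocUnit` expose the pure per-step
updates the network engine integrates (useful for unit tests and
single-cell protocols); ``simulate_grc`` / ``fi_curve`` run calibration
protocols through the same compiled kernel as the full network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .params import GocParams, GrcParams, MgBlockParams, ModelParams, SomaParams
from .raster import SpikeRaster
from .synapses import DualExpState, nmda_mg_block

__all__ = [
    "GateTables",
    "build_gate_tables",
    "rate_functions",
    "GrcUnit",
    "GocUnit",
    "simulate_grc",
    "fi_curve",
    "SPIKE_THRESHOLD_MV",
    "LOCKOUT_MS",
]

#: spike detection: upward crossing of this potential, with a lockout
SPIKE_THRESHOLD_MV = 0.0
LOCKOUT_MS = 1.0

_V_MIN, _V_MAX, _DV = -120.0, 60.0, 0.05


def rate_functions(v: np.ndarray) -> dict[str, np.ndarray]:
    """Traub–Miles opening/closing rates (1/ms) at membrane potential v (mV)."""
    v = np.asarray(v, dtype=float)

    def _safe_ratio(x, scale):
        # x / (1 - exp(-x/scale)), with the x -> 0 limit equal to scale
        out = np.where(np.abs(x) < 1e-9, scale,
                       x / (1.0 - np.exp(-np.where(np.abs(x) < 1e-9, 1.0, x)
                                         / scale)))
        return out

    am = 0.32 * _safe_ratio(v + 54.0, 4.0)
    bm = 0.28 * _safe_ratio(-(v + 27.0), 5.0)
    ah = 0.128 * np.exp(-(v + 50.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
    an = 0.032 * _safe_ratio(v + 52.0, 5.0)
    bn = 0.5 * np.exp(-(v + 57.0) / 40.0)
    return {"am": am, "bm": bm, "ah": ah, "bh": bh, "an": an, "bn": bn}


@dataclass(frozen=True)
class GateTables:
    """x_inf and exp(-dt/tau) for the m, h, n gates on a uniform V grid."""

    v0: float
    inv_dv: float
    dt_ms: float
    minf: np.ndarray
    mfac: np.ndarray
    hinf: np.ndarray
    hfac: np.ndarray
    ninf: np.ndarray
    nfac: np.ndarray

    def steady_state(self, v: float) -> tuple[float, float, float]:
        x = (v - self.v0) * self.inv_dv
        i = int(np.clip(x, 0, self.minf.size - 1))
        return float(self.minf[i]), float(self.hinf[i]), float(self.ninf[i])


_TABLE_CACHE: dict[float, GateTables] = {}


def build_gate_tables(dt_ms: float) -> GateTables:
    if dt_ms in _TABLE_CACHE:
        return _TABLE_CACHE[dt_ms]
    v = np.arange(_V_MIN, _V_MAX + _DV / 2, _DV)
    r = rate_functions(v)
    tabs = {}
    for g, (a, b) in {"m": (r["am"], r["bm"]), "h": (r["ah"], r["bh"]),
                      "n": (r["an"], r["bn"])}.items():
        tau = 1.0 / (a + b)
        tabs[g + "inf"] = (a * tau).astype(np.float64)
        tabs[g + "fac"] = np.exp(-dt_ms / tau).astype(np.float64)
    out = GateTables(v0=_V_MIN, inv_dv=1.0 / _DV, dt_ms=dt_ms,
                     minf=tabs["minf"], mfac=tabs["mfac"],
                     hinf=tabs["hinf"], hfac=tabs["hfac"],
                     ninf=tabs["ninf"], nfac=tabs["nfac"])
    _TABLE_CACHE[dt_ms] = out
    return out


def pack_soma(par: SomaParams, dt_ms: float) -> np.ndarray:
    return np.array([
        par.capacitance_pF, par.g_leak_nS, par.e_leak_mV,
        par.g_na_nS, par.e_na_mV, par.g_kdr_nS, par.e_k_mV,
        par.ahp_increment_nS, np.exp(-dt_ms / par.ahp_tau_ms),
        par.v_shift_mV,
    ])


class GrcUnit:
    """One granule-cell cluster advanced step by step.

    ``step(i_ext_pA, n_inhibitory_spikes)`` advances one time step and
    returns True on a spike.  The GABA_A conductance is driven by the
    number of presynaptic Golgi spikes arriving that step.
    """

    def __init__(self, params: GrcParams, dt_us: float = 20.0,
                 integrator: str = "cn"):
        self.p = params
        self.dt_ms = dt_us * 1e-3
        self.tables = build_gate_tables(self.dt_ms)
        self._par = pack_soma(params.soma, self.dt_ms)
        self._integrator = {"cn": 0, "exp_euler": 1}[integrator]
        self.gaba = DualExpState(params.gaba, self.dt_ms)
        self.reset()

    def reset(self, v: float | None = None) -> None:
        self.v = self.p.soma.e_leak_mV if v is None else v
        self.m, self.h, self.n = self.tables.steady_state(
            self.v - self.p.soma.v_shift_mV)
        self.ahp = 0.0
        self.gaba.r = self.gaba.d = 0.0
        self._lock = 0

    def step(self, i_ext_pA: float = 0.0, n_inh_spikes: int = 0) -> bool:
        t = self.tables
        par = self._par
        x = (self.v - par[9] - t.v0) * t.inv_dv
        i = int(np.clip(x, 0, t.minf.size - 2))
        w = np.clip(x - i, 0.0, 1.0)

        def lk(tab):
            return tab[i] * (1 - w) + tab[i + 1] * w

        self.m = lk(t.minf) + (self.m - lk(t.minf)) * lk(t.mfac)
        self.h = lk(t.hinf) + (self.h - lk(t.hinf)) * lk(t.hfac)
        self.n = lk(t.ninf) + (self.n - lk(t.ninf)) * lk(t.nfac)
        gna = par[3] * self.m ** 3 * self.h
        gk = par[5] * self.n ** 4
        g_gaba = max(self.gaba.conductance, 0.0)
        G = par[1] + gna + gk + self.ahp + g_gaba
        I = (par[1] * par[2] + gna * par[4] + gk * par[6] + self.ahp * par[6]
             + g_gaba * self.p.gaba.reversal + i_ext_pA)
        if self._integrator == 0:
            cdt = par[0] / self.dt_ms
            vnew = (self.v * (cdt - 0.5 * G) + I) / (cdt + 0.5 * G)
        else:
            vinf = I / G
            vnew = vinf + (self.v - vinf) * np.exp(-self.dt_ms * G / par[0])
        spike = False
        if self._lock > 0:
            self._lock -= 1
        elif self.v < SPIKE_THRESHOLD_MV and vnew >= SPIKE_THRESHOLD_MV:
            spike = True
            self._lock = int(round(LOCKOUT_MS / self.dt_ms))
        self.v = vnew
        self.ahp *= par[8]
        if spike:
            self.ahp += par[7]
        self.gaba.step(n_inh_spikes)
        return spike


class GocUnit:
    """One two-compartment Golgi cell advanced step by step.

    ``step(n_exc_spikes)`` feeds that many parallel-fiber spikes to the
    dendritic AMPA and NMDA synapses, advances soma and dendrite one step
    with axial coupling, and returns True on a somatic spike.  The NMDA
    conductance is gated by the Mg2+ block evaluated at the dendritic
    potential.
    """

    def __init__(self, params: GocParams, mg_block: MgBlockParams | None = None,
                 dt_us: float = 20.0, e_leak_mV: float | None = None,
                 integrator: str = "cn"):
        self.p = params
        self.mg = mg_block if mg_block is not None else MgBlockParams()
        self.dt_ms = dt_us * 1e-3
        self.tables = build_gate_tables(self.dt_ms)
        self._par = pack_soma(params.soma, self.dt_ms)
        self._integrator = {"cn": 0, "exp_euler": 1}[integrator]
        self.e_leak = (params.soma.e_leak_mV if e_leak_mV is None
                       else e_leak_mV)
        self.ampa = DualExpState(params.ampa, self.dt_ms)
        self.nmda = DualExpState(params.nmda, self.dt_ms)
        self.reset()

    def reset(self) -> None:
        self.vs = self.vd = self.e_leak
        self.m, self.h, self.n = self.tables.steady_state(
            self.vs - self.p.soma.v_shift_mV)
        self.ahp = 0.0
        self.ampa.r = self.ampa.d = 0.0
        self.nmda.r = self.nmda.d = 0.0
        self._lock = 0

    @property
    def nmda_open_fraction(self) -> float:
        return nmda_mg_block(self.vd, self.mg)

    def step(self, n_exc_spikes: int = 0, i_ext_pA: float = 0.0) -> bool:
        t = self.tables
        par = self._par
        p = self.p
        x = (self.vs - par[9] - t.v0) * t.inv_dv
        i = int(np.clip(x, 0, t.minf.size - 2))
        w = np.clip(x - i, 0.0, 1.0)

        def lk(tab):
            return tab[i] * (1 - w) + tab[i + 1] * w

        self.m = lk(t.minf) + (self.m - lk(t.minf)) * lk(t.mfac)
        self.h = lk(t.hinf) + (self.h - lk(t.hinf)) * lk(t.hfac)
        self.n = lk(t.ninf) + (self.n - lk(t.ninf)) * lk(t.nfac)
        gna = par[3] * self.m ** 3 * self.h
        gk = par[5] * self.n ** 4
        Gs = par[1] + gna + gk + self.ahp
        Is = (par[1] * self.e_leak + gna * par[4] + gk * par[6]
              + self.ahp * par[6] + i_ext_pA)
        g_a = max(self.ampa.conductance, 0.0)
        g_n = max(self.nmda.conductance, 0.0) * self.nmda_open_fraction
        Gd = p.dend_g_leak_nS + g_a + g_n
        Id = (p.dend_g_leak_nS * self.e_leak + g_a * p.ampa.reversal
              + g_n * p.nmda.reversal)
        gc = p.axial_g_nS
        dt = self.dt_ms
        if self._integrator == 0:
            a11 = par[0] / dt + 0.5 * (Gs + gc)
            a22 = p.dend_capacitance_pF / dt + 0.5 * (Gd + gc)
            a12 = -0.5 * gc
            b1 = self.vs * (par[0] / dt - 0.5 * (Gs + gc)) \
                + 0.5 * gc * self.vd + Is
            b2 = self.vd * (p.dend_capacitance_pF / dt - 0.5 * (Gd + gc)) \
                + 0.5 * gc * self.vs + Id
            det = a11 * a22 - a12 * a12
            vs_new = (b1 * a22 - a12 * b2) / det
            vd_new = (a11 * b2 - a12 * b1) / det
        else:
            gs_tot = Gs + gc
            vs_inf = (Is + gc * self.vd) / gs_tot
            vs_new = vs_inf + (self.vs - vs_inf) * np.exp(-dt * gs_tot / par[0])
            gd_tot = Gd + gc
            vd_inf = (Id + gc * self.vs) / gd_tot
            vd_new = vd_inf + (self.vd - vd_inf) * np.exp(
                -dt * gd_tot / p.dend_capacitance_pF)
        spike = False
        if self._lock > 0:
            self._lock -= 1
        elif self.vs < SPIKE_THRESHOLD_MV and vs_new >= SPIKE_THRESHOLD_MV:
            spike = True
            self._lock = int(round(LOCKOUT_MS / self.dt_ms))
        self.vs, self.vd = vs_new, vd_new
        self.ahp *= par[8]
        if spike:
            self.ahp += par[7]
        self.ampa.step(n_exc_spikes)
        self.nmda.step(n_exc_spikes)
        return spike


def simulate_grc(params: GrcParams | ModelParams, i_pA: float,
                 duration_s: float = 2.0, dt_us: float = 20.0,
                 integrator: str = "cn",
                 record_v: bool = False) -> SpikeRaster | tuple[SpikeRaster, np.ndarray]:
    """A single disinhibited granule cell under constant current injection.

    The calibration anchor protocol: with the default parameters and
    i_pA = 10.7 this fires at ~44 spikes/s.
    """
    if isinstance(params, ModelParams):
        params = params.grc
    dt_ms = dt_us * 1e-3
    n_steps = int(round(duration_s * 1e3 / dt_ms))
    tabs = build_gate_tables(dt_ms)
    par = pack_soma(params.soma, dt_ms)
    i_ext = np.full(n_steps, float(i_pA))
    g_exc = np.zeros(n_steps)
    sp_step = np.zeros(int(duration_s * 600) + 16, np.int64)
    v_trace = np.zeros(n_steps if record_v else 1)
    status, at, count = _kernels.run_single_soma(
        dt_ms, n_steps, {"cn": 0, "exp_euler": 1}[integrator],
        int(round(LOCKOUT_MS / dt_ms)),
        tabs.v0, tabs.inv_dv, tabs.minf, tabs.mfac, tabs.hinf, tabs.hfac,
        tabs.ninf, tabs.nfac,
        par, i_ext, g_exc, 0.0, params.soma.e_leak_mV,
        sp_step, record_v, v_trace)
    if status == _kernels.ERR_NONFINITE:
        raise FloatingPointError(f"non-finite membrane state at step {at}")
    if status == _kernels.ERR_SPIKE_OVERFLOW:
        raise RuntimeError(f"spike buffer overflow at step {at}")
    times = sp_step[:count] * dt_ms * 1e-3
    raster = SpikeRaster(np.zeros(count, np.int64), times, 1, duration_s,
                         population="grc", meta={"i_pA": float(i_pA)})
    return (raster, v_trace) if record_v else raster


def fi_curve(params: GrcParams | ModelParams, currents_pA: np.ndarray,
             duration_s: float = 2.0, dt_us: float = 20.0) -> np.ndarray:
    """Firing rate (spikes/s) of a disinhibited grc per injected current."""
    return np.array([
        simulate_grc(params, float(i), duration_s, dt_us).n_events / duration_s
        for i in np.asarray(currents_pA, dtype=float)
    ])
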