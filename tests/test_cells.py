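"""Single-cell behaviour: granule-cell anchor, Golgi two-compartment dynamics."""

from dataclasses import replace

import numpy as np
import pytest

import granulayer as gl
from granulayer.cells import GocUnit, GrcUnit, fi_curve, simulate_grc


def test_grc_silent_without_input(params):
    raster = simulate_grc(params, 0.0, 2.0)
    assert raster.n_events == 0


def test_grc_calibration_anchor(params):
    """Disinhibited grc at a constant 10.7 pA fires at 44 +- 5 spikes/s."""
    raster = simulate_grc(params, 10.7, 2.0)
    assert raster.n_events / 2.0 == pytest.approx(44.0, abs=5.0)


def test_grc_fi_curve_monotone(params):
    rates = fi_curve(params, [0.0, 5.0, 10.7, 20.0, 30.0, 45.0, 60.0],
                     duration_s=1.0)
    assert np.all(np.diff(rates) >= 0.0)
    assert rates[0] == 0.0 and rates[-1] > 100.0


def test_membrane_relaxation_time_constant(params):
    """With all channels frozen the soma relaxes to the leak reversal
    exponentially with tau = C / g_leak."""
    soma = replace(params.grc.soma, g_na_nS=0.0, g_kdr_nS=0.0,
                   ahp_increment_nS=0.0)
    p = replace(params.grc, soma=soma)
    unit = GrcUnit(p, dt_us=20.0)
    unit.reset(v=-50.0)
    tau = soma.capacitance_pF / soma.g_leak_nS
    v0, el = -50.0, soma.e_leak_mV
    trace = []
    for k in range(int(round(10.0 / unit.dt_ms))):
        unit.step(0.0)
        trace.append(unit.v)
    t = (np.arange(len(trace)) + 1) * unit.dt_ms
    expected = el + (v0 - el) * np.exp(-t / tau)
    assert np.max(np.abs(np.array(trace) - expected)) < 0.02


def test_goc_silent_at_rest(params):
    """Within the -60..-50 mV leak-reversal band the Goc stays quiescent."""
    for el in (-60.0, -55.0, -50.0):
        unit = GocUnit(params.goc, params.mg_block, dt_us=50.0, e_leak_mV=el)
        spikes = sum(unit.step() for _ in range(int(1e6 / 50)))  # 1 s
        assert spikes == 0


def test_goc_fires_on_coincident_volley(params):
    """A volley of coincident PF spikes drives a somatic spike through the
    dendrite; a single PF spike does not."""
    unit = GocUnit(params.goc, params.mg_block, dt_us=50.0, e_leak_mV=-55.0)
    fired = False
    for k in range(int(0.3e6 / 50)):
        fired |= unit.step(n_exc_spikes=20 if k == 2000 else 0)
    assert fired
    unit.reset()
    fired = False
    for k in range(int(0.3e6 / 50)):
        fired |= unit.step(n_exc_spikes=1 if k == 2000 else 0)
    assert not fired


def test_goc_nmda_sustains_dendritic_depolarization(params):
    """With NMDA, sustained PF drive holds the dendrite depolarized long
    after the AMPA transients (100 ms decay); without NMDA it does not."""
    mg = params.mg_block

    def dend_tail(goc_params):
        unit = GocUnit(goc_params, mg, dt_us=50.0, e_leak_mV=-55.0)
        # 300 ms of 500 Hz PF drive, then measure the dendrite 50 ms later
        for k in range(int(0.35e6 / 50)):
            drive = 1 if (k < 6000 and k % 40 == 0) else 0
            unit.step(n_exc_spikes=drive)
        return unit.vd

    with_nmda = dend_tail(params.goc)
    without = dend_tail(replace(params.goc,
                                nmda=replace(params.goc.nmda,
                                             peak_conductance=0.0)))
    assert with_nmda > without + 2.0


def test_goc_dendrite_isolation_from_somatic_ahp(params):
    """A somatic AHP event attenuates an NMDA-depolarized dendrite by < 50%."""
    unit = GocUnit(params.goc, params.mg_block, dt_us=50.0, e_leak_mV=-55.0)
    # drive the dendrite into sustained depolarization
    for k in range(int(0.3e6 / 50)):
        unit.step(n_exc_spikes=1 if k % 20 == 0 else 0)
    el = unit.e_leak
    depol_before = unit.vd - el
    # inject a somatic AHP event directly
    unit.ahp += params.goc.soma.ahp_increment_nS
    vd_min = unit.vd
    for k in range(int(0.02e6 / 50)):  # 20 ms of AHP sag
        unit.step(n_exc_spikes=1 if k % 20 == 0 else 0)
        vd_min = min(vd_min, unit.vd)
    attenuation = (depol_before - (vd_min - el)) / depol_before
    assert attenuation < 0.5


def test_grc_unit_matches_engine_kernel(params):
    """The per-step Python unit and the compiled kernel integrate the same
    model: identical spike count for the anchor protocol."""
    unit = GrcUnit(params.grc, dt_us=20.0)
    n = int(0.5e6 / 20)  # 0.5 s
    count = sum(unit.step(10.7) for _ in range(n))
    raster = simulate_grc(params, 10.7, 0.5)
    assert count == raster.n_events
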