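"""Eyeblink-conditioning readout: LTD rule, PC calibration, learned pause."""

import numpy as np
import pytest

import granulayer as gl
from granulayer.conditioning import (LTD_WINDOWS, PcParams, apply_ltd,
                                     max_firing_rate, no_cs_control,
                                     run_conditioned_pc, run_pc)
from granulayer.fixtures import FixtureSpec, poisson_raster
from granulayer.raster import SpikeRaster


def _raster(ids, times, n, dur):
    return SpikeRaster(np.array(ids), np.array(times), n, dur)


def test_ltd_zeroes_only_window_spikes():
    # US at 1.0 s; window [0.9, 0.95]
    r = _raster([0, 1, 2], [0.93, 0.80, 0.97], 3, 2.0)
    w = apply_ltd(r, cs_onset=0.0, isi=1.0)
    assert w.w.tolist() == [0.0, 1.0, 1.0]
    assert w.n_depressed == 1


def test_ltd_idempotent():
    r = _raster([0, 1], [0.93, 0.50], 2, 2.0)
    w1 = apply_ltd(r, 0.0, 1.0)
    w2 = apply_ltd(r, 0.0, 1.0, weights=w1)
    assert np.array_equal(w1.w, w2.w)


def test_ltd_window_outside_raster():
    r = _raster([0], [0.01], 1, 0.5)
    with pytest.raises(ValueError):
        apply_ltd(r, 0.0, 0.05)


def test_ltd_poisson_fraction_matches_analytic():
    """P(>=1 spike in a 50 ms window) = 1 - exp(-rate * 0.05)."""
    rate = 20.0
    r = poisson_raster(FixtureSpec("poisson", rate=rate, n_neurons=2048,
                                   duration=2.0, seed=13))
    w = apply_ltd(r, 0.0, 1.0)
    expected = 1.0 - np.exp(-rate * 0.05)
    frac = w.n_depressed / 2048
    assert frac == pytest.approx(expected, abs=0.03)


def test_alternative_ltd_window_presets():
    assert LTD_WINDOWS["default"] == (0.05, 0.1)
    r = _raster([0], [0.85], 1, 2.0)
    w = apply_ltd(r, 0.0, 1.0, window=LTD_WINDOWS["chen_thompson"])
    assert w.w[0] == 0.0  # 150 ms pre-US falls inside [0, 0.2]


def test_max_firing_rate_sliding_window():
    r = _raster([0] * 5, [0.10, 0.12, 0.14, 0.16, 0.90], 1, 1.0)
    assert max_firing_rate(r, window_s=0.1) == pytest.approx(40.0)
    assert max_firing_rate(_raster([], [], 1, 1.0)) == 0.0


def test_pc_calibration_hits_target(calibrated_pc, cs_raster):
    """Criterion: CS-driven maximum PC rate lands at 100 +- 2 spikes/s."""
    rate = max_firing_rate(run_pc(calibrated_pc, cs_raster))
    assert rate == pytest.approx(100.0, abs=2.0)


def test_pc_rate_monotone_in_conductance(calibrated_pc, cs_raster):
    from dataclasses import replace
    doubled = replace(calibrated_pc, pf_peak_nS=2 * calibrated_pc.pf_peak_nS)
    assert max_firing_rate(run_pc(doubled, cs_raster)) > 100.0


def test_pc_silent_without_drive(calibrated_pc, cs_raster):
    silent = run_pc(calibrated_pc, cs_raster, weights=np.zeros(1024))
    assert silent.n_events == 0


def test_conditioned_pause_tracks_isi(calibrated_pc, cs_raster):
    """The learned pause ends later for longer inter-stimulus intervals."""
    restarts = []
    for isi in (0.5, 0.75, 1.0):
        w = apply_ltd(cs_raster, 0.0, isi)
        _, pause = run_conditioned_pc(calibrated_pc, w, cs_raster)
        assert pause[0] < isi  # firing stops before the US
        restarts.append(pause[1])
    assert restarts[0] < restarts[1] < restarts[2]


def test_no_cs_control_tracks_oscillation(calibrated_pc, sim_default):
    """Driven by the oscillatory small-current epoch, the PC bursts at the
    granular-layer rhythm."""
    small = sim_default.grc.window(0.0, 2.0, rezero=True)
    _, burst_rate = no_cs_control(calibrated_pc, small)
    f_net = gl.compute_metrics(small, (0.0, 2.0)).f_max
    assert burst_rate == pytest.approx(f_net, abs=1.5)
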