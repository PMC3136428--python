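"""Network engine: protocols, determinism, integrators, ablations."""

import numpy as np
import pytest

import granulayer as gl
from granulayer.engine import StimulusProtocol


def test_protocol_validation():
    with pytest.raises(ValueError):
        StimulusProtocol(((0.0, 1.0, 10.0), (1.5, 2.0, 5.0)))  # gap
    with pytest.raises(ValueError):
        StimulusProtocol(((0.0, 0.0, 10.0),))  # empty segment
    with pytest.raises(ValueError):
        StimulusProtocol(((0.0, 1.0, np.inf),))
    p = gl.default_protocol()
    assert p.duration == 6.0
    steps = p.current_steps(1.0)
    assert steps[0] == 10.7 and steps[2500] == 22.7 and steps[-1] == 10.7


def test_default_protocol_truncation():
    p = gl.default_protocol(duration_s=4.0)
    assert p.duration == 4.0
    assert p.segments[-1] == (2.0, 4.0, 22.7)


def test_zero_current_gives_silent_network(toy_graph, params):
    res = gl.run_protocol(toy_graph, params, gl.constant_protocol(0.0, 0.5),
                          seed=0)
    assert res.grc.n_events == 0


def test_determinism_same_seed(toy_graph, params):
    a = gl.run_protocol(toy_graph, params, gl.constant_protocol(10.7, 0.5),
                        seed=3)
    b = gl.run_protocol(toy_graph, params, gl.constant_protocol(10.7, 0.5),
                        seed=3)
    assert np.array_equal(a.grc.times, b.grc.times)
    assert np.array_equal(a.goc.ids, b.goc.ids)


def test_integrator_cross_check(toy_graph, params):
    """Crank-Nicolson at 20 us and exponential Euler at 2 us agree on spike
    times within a few ms on a toy network (trajectories graze threshold)."""
    a = gl.run_protocol(toy_graph, params, gl.constant_protocol(10.7, 0.25),
                        seed=0, integrator="cn", dt_us=20.0)
    b = gl.run_protocol(toy_graph, params, gl.constant_protocol(10.7, 0.25),
                        seed=0, integrator="exp_euler", dt_us=2.0)
    assert a.grc.n_events == b.grc.n_events
    for i in range(toy_graph.n_grc):
        ta, tb = a.grc.spike_times(i), b.grc.spike_times(i)
        assert ta.size == tb.size
        if ta.size:
            assert np.max(np.abs(ta - tb)) < 2.5e-3


def test_dt_convergence(params):
    """Halving the step changes the population rate by < 2% (8x8 sheet)."""
    graph = gl.build_graph(gl.build_geometry(8, 8), seed=0, scheme="exact")
    rates = []
    for dt in (20.0, 10.0):
        res = gl.run_protocol(graph, params, gl.constant_protocol(10.7, 1.0),
                              seed=0, dt_us=dt)
        rates.append(res.grc.mean_rate())
    assert rates[0] == pytest.approx(rates[1], rel=0.02)


def test_unknown_integrator_rejected(toy_graph, params):
    with pytest.raises(ValueError):
        gl.run_protocol(toy_graph, params, gl.constant_protocol(1.0, 0.1),
                        integrator="rk4")


def test_voltage_trace_recording(toy_graph, params):
    res = gl.run_protocol(toy_graph, params, gl.constant_protocol(10.7, 0.2),
                          seed=0, record_v=([0], [0]), trace_decim_ms=1.0)
    assert res.traces["grc_v"].shape == (1, 200)
    assert np.all(np.isfinite(res.traces["goc_v_dend"]))


def test_ablate_inhibition_restores_intrinsic_rate(graph, params):
    """Removing Goc->grc inhibition returns grcs to the disinhibited
    44 spikes/s anchor under the small current."""
    cut = gl.ablate(graph, None, "goc_to_grc_inhibition")
    assert cut.inh_src.size == 0
    assert graph.inh_src.size > 0  # original untouched
    res = gl.run_protocol(cut, params, gl.constant_protocol(10.7, 1.0), seed=1)
    assert res.grc.mean_rate() == pytest.approx(44.0, abs=5.0)


def test_ablate_nmda_equals_infinite_mg(toy_graph, params):
    """Zeroing the NMDA conductance is the [Mg2+] -> infinity limit."""
    no_nmda = gl.ablate(None, params, "nmda")
    assert no_nmda.goc.nmda.peak_conductance == 0.0
    a = gl.run_protocol(toy_graph, no_nmda,
                        gl.constant_protocol(22.7, 0.5), seed=0)
    b = gl.run_protocol(toy_graph, params,
                        gl.constant_protocol(22.7, 0.5, mg_mM=1e9), seed=0)
    assert np.array_equal(a.grc.times, b.grc.times)


def test_ablate_unknown_name():
    with pytest.raises(ValueError):
        gl.ablate(None, None, "gap_junctions")


def test_repeat_protocol_epoch_alignment(repeat_epochs):
    ep1, ep2 = repeat_epochs
    assert ep1.duration == ep2.duration == 2.0
    assert ep1.n_events > 0 and ep2.n_events > 0
    assert ep1.times.max() < 2.0


def test_raster_round_trip(tmp_path, toy_graph, params):
    res = gl.run_protocol(toy_graph, params, gl.constant_protocol(10.7, 0.3),
                          seed=2)
    path = tmp_path / "raster.tsv"
    gl.write_raster(res.grc, path)
    back = gl.read_raster(path)
    assert back.n_neurons == res.grc.n_neurons
    assert np.allclose(back.times, res.grc.times, atol=1e-7)
    assert np.array_equal(back.ids, res.grc.ids)
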