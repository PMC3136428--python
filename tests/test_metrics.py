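"""Population metrics: binning, NAC, OI, traces, SI, PI, RI."""

import numpy as np
import pytest

import granulayer as gl
from granulayer.fixtures import (FixtureSpec, drifting_raster, periodic_raster,
                                 poisson_raster, two_trial_raster)
from granulayer.metrics import (AutocorrFunction, bin_raster, epsp_traces,
                                nac, oscillation_index, population_fluctuation,
                                pot_index, reproducibility_index, si_curve,
                                similarity_index)
from granulayer.raster import SpikeRaster


def _raster(ids, times, n, dur):
    return SpikeRaster(np.array(ids), np.array(times), n, dur)


# ---------------------------------------------------------------- binning

def test_bin_raster_single_spike():
    b = bin_raster(_raster([0], [0.010], 1, 0.1), bin_ms=1.0)
    assert b.matrix.sum() == 1
    assert b.matrix[0, 10] == 1


def test_bin_raster_binary_and_count():
    b = bin_raster(_raster([0, 0], [0.0101, 0.0105], 1, 0.1), bin_ms=1.0)
    assert b.matrix[0, 10] == 1  # two spikes in one bin stay binary
    assert b.n_bins == 100
    b2 = bin_raster(_raster([0], [0.05], 1, 0.1), bin_ms=3.0)
    assert b2.n_bins == 33  # floor(T / bin)


def test_bin_raster_rejects_bad_window():
    r = _raster([0], [0.05], 1, 0.1)
    with pytest.raises(ValueError):
        bin_raster(r, window=(0.08, 0.08))
    with pytest.raises(ValueError):
        bin_raster(r, window=(0.0, 0.5))


# --------------------------------------------- population fluctuation / NAC

def test_population_fluctuation_zero_mean_and_hand_example():
    # 3 neurons, 4 bins; counts per bin are 2,1,0,1 -> mean 1
    r = _raster([0, 1, 0, 2], [0.0005, 0.0008, 0.0015, 0.0035], 3, 0.004)
    dA = population_fluctuation(bin_raster(r, bin_ms=1.0))
    assert np.allclose(dA, [1.0, 0.0, -1.0, 0.0])
    assert abs(dA.mean()) < 1e-12


def test_nac_zero_lag_and_periodicity():
    spec = FixtureSpec("periodic", period_ms=111.0, duration=2.0, seed=0)
    dA = population_fluctuation(bin_raster(periodic_raster(spec)))
    acf = nac(dA)
    assert acf.nac[0] == pytest.approx(1.0)
    assert acf.nac[111] > 0.95
    assert acf.nac[222] > 0.95


def test_nac_poisson_near_zero():
    spec = FixtureSpec("poisson", rate=5.0, n_neurons=1024, duration=2.0, seed=3)
    dA = population_fluctuation(bin_raster(poisson_raster(spec)))
    acf = nac(dA)
    assert np.max(np.abs(acf.nac[1:])) < 0.1


def test_nac_matches_brute_force_oracle(rng):
    """The NAC pipeline equals a direct O(bins^2) autocorrelation."""
    dA = rng.normal(size=1500)
    dA -= dA.mean()
    acf = nac(dA, bin_ms=1.0, tau_max_ms=400.0)
    var = np.mean(dA * dA)
    for k in (0, 1, 17, 250, 399):
        brute = np.mean([dA[t] * dA[t + k] for t in range(dA.size - k)])
        assert acf.nac[k] == pytest.approx(brute / var, abs=1e-10)


def test_nac_degenerate_flag():
    acf = nac(np.zeros(500))
    assert acf.degenerate
    with pytest.raises(ValueError):
        oscillation_index(acf)


# ------------------------------------------------------------------- OI

def _acf(values):
    tau = np.arange(len(values), dtype=float)
    return AutocorrFunction(tau_ms=tau, nac=np.asarray(values, float),
                            window_s=2.0, bin_ms=1.0)


def test_oi_pure_cosine_is_one():
    tau = np.arange(0, 1001) * 1e-3
    oi, f = oscillation_index(_acf(np.cos(2 * np.pi * 9.0 * tau)))
    assert oi == pytest.approx(1.0, abs=1e-3)
    assert f == pytest.approx(9.0, abs=0.25)


def test_oi_delta_is_zero():
    oi, _ = oscillation_index(_acf([1.0] + [0.0] * 1000))
    assert oi == pytest.approx(0.0, abs=1e-9)


def test_oi_bounded_on_fixtures():
    for spec in (FixtureSpec("periodic", period_ms=111.0, duration=2.0),
                 FixtureSpec("poisson", rate=5.0, duration=2.0, seed=5)):
        r = (periodic_raster if spec.kind == "periodic" else poisson_raster)(spec)
        m = gl.compute_metrics(r, (0.0, 2.0))
        assert 0.0 <= m.oi <= 1.0


# ------------------------------------------------------------- EPSP traces

def test_trace_single_spike_decay():
    r = _raster([0], [0.050], 1, 0.5)
    tr = epsp_traces(r, tau_ms=30.0, dt_ms=1.0)
    k_spike = 50
    assert tr.x[0, k_spike] == pytest.approx(1.0)
    assert tr.x[0, k_spike + 30] == pytest.approx(np.exp(-1.0), rel=1e-9)
    assert tr.x[0, k_spike - 1] == 0.0


def test_trace_no_spikes_is_zero():
    tr = epsp_traces(_raster([], [], 3, 0.2))
    assert not tr.x.any()


def test_trace_superposition():
    r = _raster([0, 0], [0.050, 0.060], 1, 0.5)
    tr = epsp_traces(r, tau_ms=30.0, dt_ms=1.0)
    expected = np.exp(-20.0 / 30.0) + np.exp(-10.0 / 30.0)
    assert tr.x[0, 70] == pytest.approx(expected, rel=1e-9)


# ------------------------------------------------------------------ SI / PI

def test_si_identity_at_zero_lag():
    spec = FixtureSpec("poisson", rate=20.0, n_neurons=64, duration=1.0, seed=2)
    tr = epsp_traces(poisson_raster(spec))
    assert similarity_index(tr, 0.5, 0.0) == pytest.approx(1.0)
    tau, si, _ = si_curve(tr)
    assert si[0] == pytest.approx(1.0)


def test_si_orthogonal_populations():
    # two disjoint populations active at different times
    r = _raster([0, 1], [0.010, 0.200], 2, 0.4)
    tr = epsp_traces(r)
    assert similarity_index(tr, 0.012, 0.190) == pytest.approx(0.0, abs=1e-2)


def test_si_invariances(rng):
    """SI is invariant to neuron relabeling and uniform trace rescaling."""
    spec = FixtureSpec("drifting", rate=40.0, n_neurons=128, duration=1.0,
                       lifetime_s=0.2, seed=9)
    tr = epsp_traces(drifting_raster(spec))
    tau, si, _ = si_curve(tr)
    perm = rng.permutation(tr.x.shape[0])
    tr_perm = type(tr)(x=tr.x[perm] * 3.7, t_s=tr.t_s, tau_ms=tr.tau_ms)
    _, si_perm, _ = si_curve(tr_perm)
    assert np.allclose(si, si_perm, equal_nan=True)


def test_si_drifting_decay_matches_overlap_oracle():
    """For non-recurrent turnover with lifetime L, the active-set overlap is
    (1 - tau/L)+; SI decays on that scale and is near zero beyond L."""
    L = 0.2
    spec = FixtureSpec("drifting", rate=200.0, n_neurons=1024, duration=2.0,
                       lifetime_s=L, seed=4)
    tr = epsp_traces(drifting_raster(spec))
    tau, si, _ = si_curve(tr)
    sel = slice(1, int(L * 1000))
    assert np.all(np.diff(si[: int(L * 1000)]) < 0.05)  # monotone-ish decay
    assert si[int(1.5 * L * 1000)] < 0.15  # beyond the lifetime: no overlap


def test_pi_constant_si_is_zero():
    tau = np.arange(500, dtype=float)
    pi, fit = pot_index(tau, np.full(500, 0.7))
    assert pi == 0.0


def test_pi_normalization_height():
    """A Gaussian SI of height exactly 0.376 scores PI = 1."""
    tau = np.arange(0, 600, dtype=float)
    si = 0.376 * np.exp(-(tau ** 2) / (2 * 80.0 ** 2)) + 0.5
    pi, fit = pot_index(tau, si)
    assert pi == pytest.approx(1.0, abs=0.01)
    half = 0.188 * np.exp(-(tau ** 2) / (2 * 80.0 ** 2)) + 0.5
    pi_half, _ = pot_index(tau, half)
    assert pi_half == pytest.approx(0.5, abs=0.01)


def test_pi_ordering_periodic_vs_drifting():
    """The drifting (POT-like) fixture scores high PI; the fully periodic
    fixture scores low."""
    per = periodic_raster(FixtureSpec("periodic", period_ms=111.0,
                                      duration=2.0, participation=1.0))
    dri = drifting_raster(FixtureSpec("drifting", rate=100.0, duration=2.0,
                                      lifetime_s=0.2, seed=6))
    pi_per = gl.compute_metrics(per, (0, 2)).pi
    pi_dri = gl.compute_metrics(dri, (0, 2)).pi
    assert pi_dri > 0.5
    assert pi_per < 0.2
    assert pi_dri > pi_per


# ---------------------------------------------------------------------- RI

def test_ri_identical_trials():
    spec = FixtureSpec("poisson", rate=10.0, n_neurons=256, duration=1.0, seed=8)
    r = poisson_raster(spec)
    t, ri = reproducibility_index(epsp_traces(r), epsp_traces(r))
    assert np.nanmin(ri) == pytest.approx(1.0)


def test_ri_divergent_trials():
    spec = FixtureSpec("two_trial", rate=20.0, n_neurons=512, duration=1.0,
                       seed=11)
    r1, r2 = two_trial_raster(spec, divergence_time=0.5)
    t, ri = reproducibility_index(epsp_traces(r1), epsp_traces(r2))
    assert np.nanmean(ri[(t > 0.1) & (t < 0.45)]) > 0.99
    assert np.nanmean(ri[t > 0.7]) < 0.6


def test_ri_chance_level_for_independent_sparse_trials():
    """Fully independent sparse trials sit near the analytic chance overlap.

    For homogeneous Poisson traces the expected cosine similarity is
    E[x]^2 / E[x^2] per neuron pair structure; with rate*tau << 1 this is
    well below 0.5."""
    spec = FixtureSpec("two_trial", rate=5.0, n_neurons=1024, duration=1.0,
                       seed=12)
    r1, r2 = two_trial_raster(spec, divergence_time=0.0)
    t, ri = reproducibility_index(epsp_traces(r1), epsp_traces(r2))
    # chance level: rho = E[x]^2/E[x^2] for independent identical processes
    x = epsp_traces(r1).x
    rho = x.mean() ** 2 / np.mean(x ** 2)
    assert np.nanmean(ri[t > 0.2]) == pytest.approx(rho, abs=0.1)
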