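"""Shared fixtures: one full-network simulation per protocol, reused.

The full default network (1,024 grc clusters + 1,024 Golgi cells at a 20 us
step) costs tens of seconds per simulated second, so every protocol is run
once per session and shared by all tests that analyse it.
"""

from __future__ import annotations

import numpy as np
import pytest

import granulayer as gl


@pytest.fixture(scope="session")
def params():
    return gl.default_params()


@pytest.fixture(scope="session")
def geometry():
    return gl.build_geometry()


@pytest.fixture(scope="session")
def graph(geometry):
    return gl.default_network(seed=1)


@pytest.fixture(scope="session")
def toy_graph():
    """4x4 sheet for cheap integrator cross-checks."""
    return gl.build_graph(gl.build_geometry(4, 4), p=0.3, seed=0)


@pytest.fixture(scope="session")
def sim_default(graph, params):
    """Default 6 s protocol (10.7 / 22.7 / 10.7 pA) at [Mg2+] = 1.2 mM."""
    return gl.run_protocol(graph, params, gl.default_protocol(), seed=1)


@pytest.fixture(scope="session")
def cs_raster(graph, params):
    """2 s of constant large current: the conditioned-stimulus epoch."""
    res = gl.run_protocol(graph, params, gl.constant_protocol(22.7, 2.0),
                          seed=1)
    return res.grc


@pytest.fixture(scope="session")
def sim_high_mg(graph, params):
    """First 4 s of the default protocol with NMDA blocked at 13 mM Mg2+."""
    return gl.run_protocol(graph, params,
                           gl.default_protocol(mg_mM=13.0, duration_s=4.0),
                           seed=1)


@pytest.fixture(scope="session")
def sim_low_mg(graph, params):
    """2 s small current with NMDA channels always open (0.013 mM Mg2+)."""
    return gl.run_protocol(graph, params,
                           gl.constant_protocol(10.7, 2.0, mg_mM=0.013),
                           seed=1)


@pytest.fixture(scope="session")
def repeat_epochs(graph, params):
    """Two aligned large-current epochs from one continuous 8 s run."""
    _, ep1, ep2 = gl.run_repeat_protocol(graph, params, seed=1)
    return ep1, ep2


@pytest.fixture(scope="session")
def calibrated_pc(cs_raster):
    from granulayer.conditioning import PcParams, calibrate_pc
    return calibrate_pc(PcParams(), cs_raster)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
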