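"""Geometry and connectivity of the granular-layer sheet."""

import numpy as np
import pytest

import granulayer as gl


def test_sheet_extent_and_disk_estimate(geometry):
    assert geometry.side_lengths == (1085.0, 1085.0)
    assert gl.analytic_disk_count() == pytest.approx(68.4, abs=0.05)


def test_single_node_geometry():
    g = gl.build_geometry(1, 1, 35.0)
    assert g.n == 1
    assert np.allclose(g.positions(), [[0.0, 0.0]])


def test_nearest_neighbour_spacing(geometry):
    # brute force over all pairs: the minimum pairwise distance is the grid
    # spacing everywhere
    pos = geometry.positions()
    d2 = np.sum((pos[None, :, :] - pos[:, None, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    assert np.sqrt(d2.min(axis=1)).max() == pytest.approx(35.0)
    assert np.sqrt(d2.min(axis=1)).min() == pytest.approx(35.0)


@pytest.mark.parametrize("index,expected", [
    (16 * 32 + 16, 9 * 32),  # interior: 9 rows x 32 columns
    (0, 5 * 32),             # corner row: clipped to 5 rows
    (4 * 32, 9 * 32),        # first full-window row
])
def test_pf_candidate_counts(geometry, index, expected):
    assert gl.pf_candidates(geometry, index).size == expected


def test_pf_candidate_mean_count(geometry):
    counts = [gl.pf_candidates(geometry, j).size for j in range(geometry.n)]
    assert np.mean(counts) == pytest.approx(268.0)


def test_inh_candidate_counts(geometry):
    assert gl.inh_candidates(geometry, 16 * 32 + 16).size == 69
    assert gl.inh_candidates(geometry, 0).size < 69


def test_connectivity_means_over_seeds(geometry):
    """Bernoulli 10% thinning reproduces the reference in-degree means."""
    pf_means, inh_means = [], []
    for seed in range(10):
        g = gl.build_graph(geometry, p=0.10, seed=seed)
        pf_means.append(g.build_stats["pf_in_degree_mean"])
        inh_means.append(g.build_stats["inh_in_degree_mean"])
    assert np.mean(pf_means) == pytest.approx(26.80, abs=0.5)
    assert np.mean(inh_means) == pytest.approx(6.11, abs=0.3)


def test_binomial_in_degrees(geometry):
    """Interior-node in-degrees match Binomial(candidates, 0.1) moments."""
    g = gl.build_graph(geometry, p=0.10, seed=7)
    deg = g.pf_in_degrees().reshape(32, 32)[4:28, :].ravel()  # interior rows
    assert deg.mean() == pytest.approx(28.8, rel=0.05)
    assert deg.std() == pytest.approx(np.sqrt(288 * 0.1 * 0.9), rel=0.2)


def test_graph_determinism(geometry):
    a = gl.build_graph(geometry, seed=42)
    b = gl.build_graph(geometry, seed=42)
    assert np.array_equal(a.pf_src, b.pf_src)
    assert np.array_equal(a.inh_dst, b.inh_dst)
    c = gl.build_graph(geometry, seed=43)
    assert not (np.array_equal(a.pf_src, c.pf_src)
                and np.array_equal(a.pf_dst, c.pf_dst))


def test_exact_scheme_degrees(geometry):
    g = gl.build_graph(geometry, p=0.10, seed=0, scheme="exact")
    deg = g.pf_in_degrees().reshape(32, 32)
    assert (deg[4:28, :] == 29).all()  # round(0.1 * 288)
    assert g.build_stats["pf_in_degree_mean"] == pytest.approx(26.8, abs=0.5)
    assert g.build_stats["inh_in_degree_mean"] == pytest.approx(6.11, abs=0.4)


def test_p_limits(geometry):
    empty = gl.build_graph(geometry, p=0.0, seed=0)
    assert empty.pf_src.size == 0 and empty.inh_src.size == 0
    full = gl.build_graph(geometry, p=1.0, seed=0)
    assert full.pf_in_degrees()[16 * 32 + 16] == 288


def test_all_to_all(geometry):
    g = gl.build_all_to_all(geometry)
    assert g.pf_in_degrees()[16 * 32 + 16] == 288
    assert g.inh_in_degrees()[16 * 32 + 16] == 69
    h = gl.build_all_to_all(geometry)
    assert np.array_equal(g.pf_src, h.pf_src)


def test_graph_round_trip(tmp_path, geometry):
    g = gl.build_graph(gl.build_geometry(6, 6), seed=3)
    path = tmp_path / "graph.tsv"
    gl.write_graph(g, path)
    h = gl.read_graph(path)
    assert np.array_equal(np.sort(g.pf_src * 10000 + g.pf_dst),
                          np.sort(h.pf_src * 10000 + h.pf_dst))
    assert h.seed == 3 and h.p == 0.10


def test_csr_out_adjacency(geometry):
    g = gl.build_graph(gl.build_geometry(4, 4), p=0.5, seed=1)
    indptr, targets = g.csr_out("pf")
    for src in range(g.n_grc):
        expected = np.sort(g.pf_dst[g.pf_src == src])
        assert np.array_equal(np.sort(targets[indptr[src]:indptr[src + 1]]),
                              expected)


def test_default_params_yaml_round_trip():
    """The shipped defaults file reproduces the in-code parameter set."""
    from importlib import resources

    import granulayer as gl
    from granulayer.params import load_params

    with resources.files("granulayer").joinpath("defaults.yaml").open() as fh:
        loaded = load_params(fh)
    assert loaded == gl.default_params()
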