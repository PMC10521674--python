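"""Network coefficients against worked values and a networkx oracle."""

import networkx as nx
import numpy as np
import pytest

from nphkit.errors import InvariantError
from nphkit.netmetrics import (
    FEATURE_ORDER_25,
    FEATURE_ORDER_26,
    assemble_features,
    assortativity,
    char_path_length,
    clustering_average,
    density,
    diameter,
    global_efficiency,
    radius,
    rich_club,
    small_worldness,
    transitivity,
)
from nphkit.roa import binarize
from nphkit.types import ConnectivityMatrix


def adj(edges, n):
    W = np.zeros((n, n))
    for i, j in edges:
        W[i, j] = W[j, i] = 1.0
    return W


P3 = adj([(0, 1), (1, 2)], 3)
P4 = adj([(0, 1), (1, 2), (2, 3)], 4)
C5 = adj([(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)], 5)
K4 = adj([(i, j) for i in range(4) for j in range(i + 1, 4)], 4)
K4_MINUS = K4.copy()
K4_MINUS[0, 1] = K4_MINUS[1, 0] = 0
STAR4 = adj([(0, 1), (0, 2), (0, 3)], 4)
TRIANGLE = adj([(0, 1), (1, 2), (2, 0)], 3)
TWO_EDGES = adj([(0, 1), (2, 3)], 4)
TWO_K3 = adj([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)], 6)
K6 = adj([(i, j) for i in range(6) for j in range(i + 1, 6)], 6)


class TestWorkedValues:
    @pytest.mark.parametrize("W,expected", [
        (K4, 1.0), (np.zeros((4, 4)), 0.0), (P3, 2 / 3),
    ])
    def test_density(self, W, expected):
        assert density(W, "binary") == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("W,expected", [
        (TRIANGLE, 1.0), (STAR4, 0.0), (K4_MINUS, 5 / 6),
    ])
    def test_clustering(self, W, expected):
        assert clustering_average(W, "binary") == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("W,expected", [
        (TRIANGLE, 1.0), (P3, 0.0), (K4_MINUS, 0.75),
    ])
    def test_transitivity(self, W, expected):
        assert transitivity(W, "binary") == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("W,expected", [
        (K4, 1.0), (P3, 4 / 3), (TWO_EDGES, 1.0),  # largest-component rule
    ])
    def test_char_path_length(self, W, expected):
        assert char_path_length(W, "binary") == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("W,expected", [
        (K4, 1.0), (np.zeros((3, 3)), 0.0), (P3, 5 / 6),
    ])
    def test_global_efficiency(self, W, expected):
        assert global_efficiency(W, "binary") == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("W,diam,rad", [
        (P4, 3, 2), (K4, 1, 1), (C5, 2, 2),
    ])
    def test_diameter_radius(self, W, diam, rad):
        assert diameter(W, "binary") == diam
        assert radius(W, "binary") == rad

    def test_star_assortativity_is_minus_one(self):
        assert assortativity(STAR4, "binary") == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("W", [C5, TWO_K3])
    def test_regular_graph_assortativity_substitutes_zero(self, W):
        assert assortativity(W, "binary") == 0.0

    def test_rich_club_complete_graph(self):
        assert rich_club(K6, 5, "binary") == 1.0

    def test_rich_club_above_max_degree_is_zero(self):
        assert rich_club(K6, 6, "binary") == 0.0

    def test_small_world_complete_graph_is_one(self):
        assert small_worldness(K6, "binary", n_null=5, seed=0) == pytest.approx(1.0)

    def test_small_world_ring_lattice_exceeds_one(self):
        G = nx.watts_strogatz_graph(20, 4, p=0.0, seed=0)  # pure lattice
        W = nx.to_numpy_array(G)
        assert small_worldness(W, "binary", n_null=20, seed=1) > 1.0

    def test_small_world_deterministic_per_seed(self):
        a = small_worldness(C5, "binary", n_null=10, seed=3)
        b = small_worldness(C5, "binary", n_null=10, seed=3)
        assert a == b


def _brute_force_rich_club(W, k):
    deg = (W > 0).sum(axis=1)
    R = np.flatnonzero(deg >= k)
    if R.size <= 1:
        return 0.0
    edges = sum(
        1 for a in range(R.size) for b in range(a + 1, R.size) if W[R[a], R[b]] > 0
    )
    return edges / (R.size * (R.size - 1) / 2)


@pytest.fixture(scope="module")
def graphs():
    out = []
    rng = np.random.default_rng(2024)
    for _ in range(100):
        n = int(rng.integers(4, 21))
        p = float(rng.uniform(0.15, 0.7))
        G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        out.append(nx.to_numpy_array(G))
    return out


class TestNetworkxOracle:
    """Binary coefficients match independent references on 100 seeded graphs."""

    def test_all_binary_metrics_match_reference(self, graphs):
        for W in graphs:
            G = nx.from_numpy_array(W)
            n = W.shape[0]
            assert density(W, "binary") == pytest.approx(nx.density(G), abs=1e-9)
            assert clustering_average(W, "binary") == pytest.approx(
                nx.average_clustering(G), abs=1e-9)
            assert transitivity(W, "binary") == pytest.approx(
                nx.transitivity(G), abs=1e-9)
            assert global_efficiency(W, "binary") == pytest.approx(
                nx.global_efficiency(G), abs=1e-9)
            comp = max(nx.connected_components(G), key=len)
            if len(comp) >= 2:
                sub = G.subgraph(comp)
                assert char_path_length(W, "binary") == pytest.approx(
                    nx.average_shortest_path_length(sub), abs=1e-9)
                assert diameter(W, "binary") == pytest.approx(nx.diameter(sub), abs=1e-9)
                assert radius(W, "binary") == pytest.approx(nx.radius(sub), abs=1e-9)
            r_nx = nx.degree_assortativity_coefficient(G) if G.number_of_edges() > 1 else np.nan
            if np.isfinite(r_nx):
                assert assortativity(W, "binary") == pytest.approx(r_nx, abs=1e-9)
            for k in range(1, 6):
                assert rich_club(W, k, "binary") == pytest.approx(
                    _brute_force_rich_club(W, k), abs=1e-9)

    def test_crafted_rich_club_equals_enumeration(self):
        rng = np.random.default_rng(8)
        W = (rng.random((8, 8)) > 0.5).astype(float)
        W = np.triu(W, 1)
        W = W + W.T
        assert rich_club(W, 3, "binary") == pytest.approx(
            _brute_force_rich_club(W, 3), abs=1e-12)


@pytest.fixture(scope="module")
def W():
    rng = np.random.default_rng(7)
    W = rng.random((12, 12)) * (rng.random((12, 12)) > 0.5)
    W = np.triu(W, 1)
    return W + W.T


class TestScaleAndPermutation:

    def test_binary_metrics_ignore_weight_scaling(self, W):
        for fn in (density, clustering_average, transitivity, char_path_length,
                   global_efficiency, diameter, radius, assortativity):
            assert fn(W, "binary") == pytest.approx(fn(3.7 * W, "binary"), abs=1e-12)

    def test_weighted_density_scales_linearly(self, W):
        assert density(4.0 * W, "weighted") == pytest.approx(
            4.0 * density(W, "weighted"), rel=1e-12)

    def test_weighted_path_length_scales_inversely(self, W):
        assert char_path_length(4.0 * W, "weighted") == pytest.approx(
            char_path_length(W, "weighted") / 4.0, rel=1e-12)

    def test_triangle_metrics_are_scale_invariant(self, W):
        for fn in (clustering_average, transitivity):
            assert fn(2.5 * W, "weighted") == pytest.approx(fn(W, "weighted"), rel=1e-12)

    def test_permutation_invariance(self, W):
        rng = np.random.default_rng(1)
        perm = rng.permutation(W.shape[0])
        Wp = W[np.ix_(perm, perm)]
        for fn in (density, clustering_average, transitivity, char_path_length,
                   global_efficiency, diameter, radius, assortativity):
            for variant in ("binary", "weighted"):
                assert fn(Wp, variant) == pytest.approx(fn(W, variant), abs=1e-9)


@pytest.fixture(scope="module")
def conn():
    rng = np.random.default_rng(4)
    W = rng.integers(0, 5, size=(15, 15)).astype(float)
    W = np.triu(W, 1)
    W = W + W.T
    return ConnectivityMatrix(weights=W)


class TestAssembleFeatures:

    def test_default_vector_has_26_named_entries(self, conn):
        feats = assemble_features(conn, seed=0)
        assert len(feats) == 26
        assert feats.names == FEATURE_ORDER_26

    def test_25_feature_mode_drops_weighted_density(self, conn):
        feats = assemble_features(conn, seed=0, feature_mode="25")
        assert len(feats) == 25
        assert feats.names == FEATURE_ORDER_25

    def test_zero_matrix_gives_flagged_zero_vector(self):
        feats = assemble_features(ConnectivityMatrix(weights=np.zeros((10, 10))), seed=0)
        assert np.array_equal(feats.to_array(), np.zeros(26))
        assert all(feats.degenerate.values())

    def test_entries_match_single_metric_calls(self, conn):
        feats = assemble_features(conn, n_null=10, seed=4)
        mb = binarize(conn)
        assert feats.values["density_binary"] == density(mb, "binary")
        assert feats.values["density_weighted"] == density(conn, "weighted")
        assert feats.values["clustering_weighted"] == clustering_average(conn, "weighted")
        assert feats.values["char_path_binary"] == char_path_length(mb, "binary")
        assert feats.values["small_world_weighted"] == small_worldness(
            conn, "weighted", n_null=10, seed=4)
        assert feats.values["assortativity_binary"] == assortativity(mb, "binary")
        assert feats.values["rich_club_k5_weighted"] == rich_club(conn, 5, "weighted")

    def test_degenerate_precondition_raises_in_single_call(self):
        with pytest.raises(InvariantError):
            char_path_length(np.zeros((5, 5)), "binary")
        with pytest.raises(InvariantError):
            diameter(np.zeros((5, 5)), "binary")
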