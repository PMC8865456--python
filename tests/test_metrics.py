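"""Weighted graph metrics against hand computations and brute-force oracles."""
import numpy as np
import pandas as pd
import pytest

from conftest import random_weight_matrix
from klsenet.exceptions import InputError, UndefinedMetricError
from klsenet.metrics import (
    betweenness,
    characteristic_path_length,
    compute_nodal_metrics,
    count_hubs_by_scope,
    distance_matrix,
    identify_hubs,
    local_efficiency,
    mean_strength,
    threshold_edges,
    weighted_clustering,
)
from oracles import (
    betweenness_enumeration,
    floyd_warshall,
    local_efficiency_brute,
    onnela_clustering,
)


def three_node_fixture():
    w = np.array([[1.0, 0.2, 0.4], [0.2, 1.0, 0.6], [0.4, 0.6, 1.0]])
    return w


class TestMeanStrength:
    def test_within_mean(self):
        assert mean_strength(three_node_fixture()) == pytest.approx(0.4)

    def test_between_sets(self):
        assert mean_strength(three_node_fixture(), [0], [1, 2]) == pytest.approx(0.3)

    def test_block_matrix_within_vs_between(self):
        w = np.full((6, 6), 0.2)
        w[:3, :3] = 0.8
        w[3:, 3:] = 0.8
        np.fill_diagonal(w, 1.0)
        assert mean_strength(w, [0, 1, 2]) == pytest.approx(0.8)
        assert mean_strength(w, [0, 1, 2], [3, 4, 5]) == pytest.approx(0.2)

    def test_singleton_within_rejected(self):
        with pytest.raises(UndefinedMetricError):
            mean_strength(three_node_fixture(), [0])

    def test_overlapping_sets_rejected(self):
        with pytest.raises(InputError):
            mean_strength(three_node_fixture(), [0, 1], [1, 2])


class TestDistances:
    def test_unit_complete_graph(self):
        w = np.ones((4, 4))
        d = distance_matrix(w)
        assert np.array_equal(d, 1.0 - np.eye(4))

    def test_three_node_hand_case(self):
        """w12=1, w13=0.5, w23=0.5: direct edges are always shortest."""
        w = np.array([[1.0, 1.0, 0.5], [1.0, 1.0, 0.5], [0.5, 0.5, 1.0]])
        d = distance_matrix(w)
        assert d[0, 1] == pytest.approx(1.0)
        assert d[0, 2] == pytest.approx(2.0)
        assert d[1, 2] == pytest.approx(2.0)

    def test_characteristic_path_length_hand_case(self):
        w = np.array([[1.0, 1.0, 0.5], [1.0, 1.0, 0.5], [0.5, 0.5, 1.0]])
        assert characteristic_path_length(w) == pytest.approx(5.0 / 3.0)

    def test_scaling_property(self):
        rng = np.random.default_rng(0)
        w = random_weight_matrix(rng, 7)
        c = 3.7
        assert characteristic_path_length(c * w) == pytest.approx(
            characteristic_path_length(w) / c, rel=1e-12
        )

    def test_nonpositive_weight_rejected(self):
        w = np.ones((3, 3))
        w[0, 1] = w[1, 0] = 0.0
        with pytest.raises(InputError):
            distance_matrix(w)


class TestClustering:
    def test_equal_weights_give_unit_clustering(self):
        w = np.full((5, 5), 0.7)
        np.fill_diagonal(w, 1.0)
        c, avg = weighted_clustering(w)
        assert np.allclose(c, 1.0) and avg == pytest.approx(1.0)

    def test_triangle_hand_value(self):
        """Triangle {1, 0.5, 0.5}: every node has C = (1*0.5*0.5)^(1/3)
        after max-normalization = 0.63."""
        w = np.array([[1.0, 1.0, 0.5], [1.0, 1.0, 0.5], [0.5, 0.5, 1.0]])
        c, _ = weighted_clustering(w)
        assert np.allclose(c, 0.25 ** (1.0 / 3.0), atol=1e-12)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(UndefinedMetricError):
            weighted_clustering(np.ones((2, 2)))


class TestLocalEfficiency:
    def test_unit_complete_graph(self):
        w = np.ones((6, 6))
        e, avg = local_efficiency(w)
        assert np.allclose(e, 1.0) and avg == pytest.approx(1.0)

    def test_three_node_hand_value(self):
        """Node 0 with neighbours 1, 2 joined by weight w23: the sum has the
        two ordered pairs, each (w01 * w02 * w23)^(1/3), over k(k-1) = 2."""
        w01, w02, w23 = 0.9, 0.6, 0.3
        w = np.array([[1.0, w01, w02], [w01, 1.0, w23], [w02, w23, 1.0]])
        e, _ = local_efficiency(w)
        assert e[0] == pytest.approx((w01 * w02 * w23) ** (1.0 / 3.0))


class TestBetweenness:
    def test_complete_equal_weights_all_zero(self):
        w = np.full((6, 6), 0.5)
        np.fill_diagonal(w, 1.0)
        assert np.allclose(betweenness(w), 0.0)

    def test_path_dominant_fixture(self):
        """Chain weights 1.0 among consecutive nodes, weak (0.1) elsewhere:
        node 1 lies on every shortest path from node 0 to nodes 2 and 3."""
        w = np.full((4, 4), 0.1)
        for i in range(3):
            w[i, i + 1] = w[i + 1, i] = 1.0
        np.fill_diagonal(w, 1.0)
        bc = betweenness(w)
        assert bc[1] > 0 and bc[2] > 0
        assert bc[0] == 0 and bc[3] == 0


@pytest.fixture(scope="module")
def graphs():
    rng = np.random.default_rng(12345)
    return [random_weight_matrix(rng, int(rng.integers(6, 11))) for _ in range(100)]


class TestOracleEquivalence:
    """All metrics equal independent brute-force oracles on 100 random
    small complete weighted graphs."""

    def test_distances_equal_floyd_warshall(self, graphs):
        for w in graphs:
            lengths = 1.0 / w
            np.fill_diagonal(lengths, 0.0)
            assert np.allclose(distance_matrix(w), floyd_warshall(lengths), atol=1e-12)

    def test_clustering_equals_triple_loop(self, graphs):
        for w in graphs:
            assert np.allclose(weighted_clustering(w)[0], onnela_clustering(w), atol=1e-12)

    def test_local_efficiency_equals_brute_force(self, graphs):
        for w in graphs:
            assert np.allclose(local_efficiency(w)[0], local_efficiency_brute(w), atol=1e-10)

    def test_betweenness_equals_path_enumeration(self, graphs):
        for w in graphs[:40]:  # enumeration oracle is the slow one
            assert np.allclose(betweenness(w), betweenness_enumeration(w), atol=1e-8)


class TestHubs:
    def make_nodal(self, n, rng):
        return pd.DataFrame(
            {
                "node_id": np.arange(1, n + 1),
                "degree": rng.uniform(1, 10, n),
                "path_length": rng.uniform(1, 3, n),
                "clustering": rng.uniform(0, 1, n),
                "betweenness": rng.uniform(0, 5, n),
            }
        )

    def test_exact_flag_counts(self):
        rng = np.random.default_rng(0)
        hubs = identify_hubs(self.make_nodal(100, rng))
        for col in ("flag_degree", "flag_path_length", "flag_clustering", "flag_betweenness"):
            assert hubs[col].sum() == 20

    def test_score_rule(self):
        rng = np.random.default_rng(1)
        hubs = identify_hubs(self.make_nodal(50, rng))
        flag_cols = ["flag_degree", "flag_path_length", "flag_clustering", "flag_betweenness"]
        assert (hubs["hub_score"] == hubs[flag_cols].sum(axis=1)).all()
        assert (hubs["is_hub"] == (hubs["hub_score"] >= 2)).all()

    def test_star_center_is_hub(self):
        """Weighted 5-node star: the strongly connected center wins degree,
        path length and betweenness (score >= 3); leaves stay below 2."""
        w = np.full((5, 5), 0.1)
        w[0, 1:] = w[1:, 0] = 0.9
        np.fill_diagonal(w, 1.0)
        hubs = identify_hubs(compute_nodal_metrics(w, include_local_efficiency=False))
        center = hubs.iloc[0]
        assert center["flag_degree"] and center["flag_path_length"] and center["flag_betweenness"]
        assert center["is_hub"] and center["hub_score"] >= 3
        assert (hubs.iloc[1:]["hub_score"] <= 1).all()

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        w = random_weight_matrix(rng, 15)
        h1 = identify_hubs(compute_nodal_metrics(w, include_local_efficiency=False))
        h2 = identify_hubs(compute_nodal_metrics(0.37 * w, include_local_efficiency=False))
        assert (h1["is_hub"] == h2["is_hub"]).all()
        assert (h1["hub_score"] == h2["hub_score"]).all()

    def test_tie_break_deterministic(self):
        """All-equal weights tie every criterion; flags still number
        round(0.2 n) and go to the lowest node ids."""
        w = np.full((10, 10), 0.5)
        np.fill_diagonal(w, 1.0)
        hubs = identify_hubs(compute_nodal_metrics(w, include_local_efficiency=False))
        for col in ("flag_degree", "flag_path_length", "flag_clustering", "flag_betweenness"):
            assert hubs[col].sum() == 2
            assert hubs.loc[hubs[col], "node_id"].tolist() == [0, 1]

    def test_too_few_nodes_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(UndefinedMetricError):
            identify_hubs(self.make_nodal(4, rng))

    def test_counts_by_scope_with_empty_network(self):
        rng = np.random.default_rng(4)
        hubs = identify_hubs(self.make_nodal(10, rng))
        parcels = pd.DataFrame(
            {
                "parcel_id": np.arange(1, 11),
                "parcel_name": [f"p{i}" for i in range(1, 11)],
                "network": ["a"] * 5 + ["b"] * 5,
            }
        )
        empty = pd.DataFrame({"parcel_id": [99], "parcel_name": ["x"], "network": ["c"]})
        parcels_with_empty = pd.concat([parcels, empty], ignore_index=True)
        hubs_sub = hubs[hubs["node_id"] <= 10]
        counts = count_hubs_by_scope(hubs_sub, parcels_with_empty)
        assert counts["c"] == 0
        assert counts["whole_brain"] == counts["a"] + counts["b"]


class TestThresholdEdges:
    def test_below_threshold_empty(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 1.0)
        assert len(threshold_edges(w, 0.8)) == 0

    def test_boundary_inclusive(self):
        w = np.eye(3)
        w[0, 1] = w[1, 0] = 0.79
        w[0, 2] = w[2, 0] = 0.80
        w[1, 2] = w[2, 1] = 0.81
        edges = threshold_edges(w, 0.80)
        assert len(edges) == 2
        assert set(edges["weight"]) == {0.80, 0.81}

    def test_bad_threshold_rejected(self):
        with pytest.raises(InputError):
            threshold_edges(np.ones((3, 3)), 0.0)


class TestSubnetworkIsolation:
    def test_induced_metrics_ignore_outside_edges(self):
        """Mutating out-of-network weights leaves within-network path
        length, clustering and efficiency unchanged."""
        rng = np.random.default_rng(5)
        w = random_weight_matrix(rng, 12)
        sub = [2, 3, 4, 5, 6]
        before = (
            characteristic_path_length(w, sub),
            weighted_clustering(w, sub)[1],
            local_efficiency(w, sub)[1],
        )
        w2 = w.copy()
        outside = [i for i in range(12) if i not in sub]
        for i in outside:  # perturb every edge touching an outside node
            for j in range(12):
                if i != j:
                    w2[i, j] = w2[j, i] = rng.uniform(0.2, 1.0)
        after = (
            characteristic_path_length(w2, sub),
            weighted_clustering(w2, sub)[1],
            local_efficiency(w2, sub)[1],
        )
        assert before == after
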