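import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import normalized_mutual_info_score

from striaparc.community import (
    NetworkAssignment,
    exclude_networks,
    louvain,
    match_networks,
    modularity,
)
from striaparc.connectivity import ConnectivityMatrix, NodeTimeSeriesMatrix, connectivity_matrix
from striaparc.io import AtlasLabels
from striaparc.synth import SyntheticConfig, generate_cortical_series


def two_cliques(n_per=5):
    """Two disconnected equal cliques with unit weights."""
    n = 2 * n_per
    W = np.zeros((n, n))
    for block in (slice(0, n_per), slice(n_per, n)):
        W[block, block] = 1.0
    np.fill_diagonal(W, 0.0)
    return W


class TestModularity:
    def test_single_community_is_zero(self, rng):
        W = np.abs(rng.standard_normal((8, 8)))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        assert modularity(W, np.zeros(8, dtype=int)) == pytest.approx(0.0, abs=1e-14)

    def test_two_cliques_closed_form(self):
        W = two_cliques(5)
        part = np.repeat([0, 1], 5)
        # brute-force evaluation of the formula: each block holds half the
        # weight, null model expects a quarter per block pair -> Q = 1/2
        assert modularity(W, part) == pytest.approx(0.5)

    def test_matches_networkx_on_random_graphs(self, rng):
        for _ in range(5):
            W = np.abs(rng.standard_normal((12, 12)))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0)
            part = rng.integers(0, 3, size=12)
            G = nx.from_numpy_array(W)
            comms = [set(np.flatnonzero(part == k)) for k in range(3) if np.any(part == k)]
            expected = nx.community.modularity(G, comms, weight="weight")
            assert modularity(W, part) == pytest.approx(expected, abs=1e-12)

    def test_planted_partition_beats_random(self, rng):
        W = two_cliques(5)
        planted = np.repeat([0, 1], 5)
        q_planted = modularity(W, planted)
        # exhaustive over all 2-labellings of 10 nodes
        best_other = max(
            modularity(W, np.array(lab))
            for lab in itertools.product([0, 1], repeat=10)
            if not np.array_equal(lab, planted) and not np.array_equal(lab, 1 - planted)
        )
        assert q_planted > best_other

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            modularity(np.zeros((4, 4)), np.zeros(4, dtype=int))


class TestLouvain:
    def test_disconnected_cliques_found_exactly(self):
        conn = ConnectivityMatrix(z=two_cliques(5), node_ids=np.arange(10))
        asg, res = louvain(conn, seed=0, n_runs=5)
        assert asg.n_communities == 2
        assert normalized_mutual_info_score(np.repeat([0, 1], 5), asg.membership) == 1.0
        assert res.Q == pytest.approx(0.5)

    def test_planted_blocks_recovered(self):
        cfg = SyntheticConfig(seed=4, n_nodes=60, n_networks=5, n_striatal_voxels=10,
                              n_timepoints=500, within_network_corr=0.6,
                              between_network_corr=0.0)
        series, part, _ = generate_cortical_series(cfg)
        conn = connectivity_matrix(
            NodeTimeSeriesMatrix(values=series, node_ids=np.arange(60))
        )
        asg, _ = louvain(conn, seed=1, n_runs=3)
        assert normalized_mutual_info_score(part, asg.membership) >= 0.95

    def test_deterministic_given_seed(self):
        conn = ConnectivityMatrix(z=two_cliques(4), node_ids=np.arange(8))
        a1, r1 = louvain(conn, seed=9, n_runs=4)
        a2, r2 = louvain(conn, seed=9, n_runs=4)
        np.testing.assert_array_equal(a1.membership, a2.membership)
        assert r1.Q == r2.Q

    def test_never_below_trivial_baselines(self, rng):
        W = np.abs(rng.standard_normal((15, 15)))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        asg, res = louvain(W, seed=3, n_runs=5)
        q_one = modularity(W, np.zeros(15, dtype=int))
        q_singletons = modularity(W, np.arange(15))
        assert res.Q >= max(q_one, q_singletons)

    def test_reported_q_consistent_with_partition(self):
        conn = ConnectivityMatrix(z=two_cliques(5), node_ids=np.arange(10))
        asg, res = louvain(conn, seed=0, n_runs=3)
        assert res.Q == pytest.approx(modularity(conn.z, asg.membership), abs=1e-12)


def _atlas_with_networks(networks):
    n = len(networks)
    labels = np.zeros((n, 1, 1), dtype=np.int64)
    labels[:, 0, 0] = np.arange(1, n + 1)
    table = pd.DataFrame(
        {"label": np.arange(1, n + 1), "name": [f"n{i}" for i in range(n)],
         "network": networks}
    ).set_index("label")
    return AtlasLabels(labels=labels, table=table, affine=np.eye(4))


class TestMatchNetworks:
    def test_identical_partition_perfect_names(self):
        ref = ["DMN"] * 3 + ["CON"] * 3 + ["VIS"] * 2
        asg = NetworkAssignment(
            membership=np.array([0] * 3 + [1] * 3 + [2] * 2),
            names={0: "community-0", 1: "community-1", 2: "community-2"},
        )
        named = match_networks(asg, _atlas_with_networks(ref))
        assert [named.names[k] for k in range(3)] == ["DMN", "CON", "VIS"]

    def test_majority_overlap_wins(self):
        ref = ["DMN"] * 4 + ["CON"]
        asg = NetworkAssignment(membership=np.zeros(5, dtype=int), names={0: "community-0"})
        named = match_networks(asg, _atlas_with_networks(ref))
        assert named.names[0] == "DMN"

    def test_hungarian_uniqueness(self):
        # both communities mostly DMN; the larger-overlap one gets the name.
        # brute-force over the 2x2 count matrix confirms the optimum.
        ref = ["DMN"] * 5 + ["CON"]
        memb = np.array([0, 0, 0, 1, 1, 1])
        counts = {(0, "DMN"): 3, (0, "CON"): 0, (1, "DMN"): 2, (1, "CON"): 1}
        best = max(
            [(counts[(0, a)] + counts[(1, b)], a, b)
             for a, b in itertools.permutations(["DMN", "CON"])],
        )
        assert (best[1], best[2]) == ("DMN", "CON")
        asg = NetworkAssignment(membership=memb, names={0: "community-0", 1: "community-1"})
        named = match_networks(asg, _atlas_with_networks(ref))
        assert named.names[0] == "DMN"
        assert named.names[1] == "CON"

    def test_no_reference_names_keeps_identity(self):
        asg = NetworkAssignment(membership=np.array([0, 1]), names={0: "community-0",
                                                                    1: "community-1"})
        atlas = _atlas_with_networks(["x", "y"])
        atlas.table = atlas.table.drop(columns="network")
        named = match_networks(asg, atlas)
        assert named.names == {0: "community-0", 1: "community-1"}


class TestExcludeNetworks:
    def _named(self):
        return NetworkAssignment(
            membership=np.arange(6),
            names={0: "DMN", 1: "SMN", 2: "CON", 3: "DAT", 4: "AUD", 5: "VIS"},
        )

    def test_exclude_visual_leaves_five_active(self):
        asg = exclude_networks(self._named(), {"VIS"})
        assert len(asg.active_networks) == 5
        assert "VIS" not in asg.active_networks

    def test_exclude_nothing_retains_all(self):
        asg = exclude_networks(self._named(), set())
        assert len(asg.active_networks) == 6

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            exclude_networks(self._named(), {"FPN"})
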