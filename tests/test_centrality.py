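"""Node and bridge centrality against exhaustive-path oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from musenet import centrality
from musenet.errors import ConfigError

TOL = 1e-10


# ---------------------------------------------------------------------------
# Brute-force oracle: enumerate every simple path
# ---------------------------------------------------------------------------

def all_shortest_paths(w):
    """Shortest distances and the set of shortest simple paths per pair.

    Enumerates every simple path with distances 1/|w|; intended for graphs
    of a handful of nodes only.
    """
    p = w.shape[0]
    best: dict[tuple[int, int], tuple[float, list[tuple[int, ...]]]] = {}
    for u in range(p):
        for v in range(p):
            if u == v:
                continue
            paths = []
            for k in range(p):
                for middle in itertools.permutations(
                        [x for x in range(p) if x not in (u, v)], k):
                    path = (u, *middle, v)
                    if all(abs(w[a, b]) > 1e-12
                           for a, b in zip(path, path[1:])):
                        d = sum(1.0 / abs(w[a, b])
                                for a, b in zip(path, path[1:]))
                        paths.append((d, path))
            if not paths:
                continue
            dmin = min(d for d, _ in paths)
            best[(u, v)] = (dmin, [pth for d, pth in paths
                                   if d <= dmin + TOL])
    return best


def oracle_node_centrality(w):
    p = w.shape[0]
    best = all_shortest_paths(w)
    strength = np.abs(w).sum(axis=1) - np.abs(np.diag(w))
    ei1 = w.sum(axis=1) - np.diag(w)
    closeness = np.zeros(p)
    betweenness = np.zeros(p)
    for i in range(p):
        dists = [best[(i, j)][0] for j in range(p)
                 if j != i and (i, j) in best]
        if dists:
            closeness[i] = 1.0 / sum(dists)
    for u in range(p):
        for v in range(u + 1, p):
            if (u, v) not in best:
                continue
            _, paths = best[(u, v)]
            for i in range(p):
                if i in (u, v):
                    continue
                through = sum(1 for pth in paths if i in pth)
                betweenness[i] += through / len(paths)
    return strength, closeness, betweenness, ei1


def oracle_bridge_centrality(w, comm):
    p = w.shape[0]
    best = all_shortest_paths(w)
    cross = np.not_equal.outer(comm, comm)
    b_strength = (np.abs(w) * cross).sum(axis=1)
    b_ei1 = (w * cross).sum(axis=1)
    b_clo = np.zeros(p)
    b_bet = np.zeros(p)
    for i in range(p):
        dists = [best[(i, j)][0] for j in range(p)
                 if cross[i, j] and (i, j) in best]
        if dists:
            b_clo[i] = 1.0 / np.mean(dists)
    for u in range(p):
        for v in range(u + 1, p):
            if not cross[u, v] or (u, v) not in best:
                continue
            _, paths = best[(u, v)]
            for i in range(p):
                if i in (u, v):
                    continue
                through = sum(1 for pth in paths if i in pth)
                b_bet[i] += through / len(paths)
    return b_strength, b_clo, b_bet, b_ei1


# ---------------------------------------------------------------------------
# Node centrality
# ---------------------------------------------------------------------------

class TestNodeCentrality:
    def test_strength_and_ei1_direct_sums(self):
        w = pd.DataFrame([[0.0, 0.3, -0.2],
                          [0.3, 0.0, 0.0],
                          [-0.2, 0.0, 0.0]],
                         index=list("XYZ"), columns=list("XYZ"))
        out = centrality.node_centrality(w)
        assert out.loc["X", "strength"] == pytest.approx(0.5)
        assert out.loc["X", "expected_influence_1"] == pytest.approx(0.1)

    def test_isolated_node_conventions(self):
        w = pd.DataFrame(np.zeros((3, 3)), index=list("XYZ"),
                         columns=list("XYZ"))
        w.loc["X", "Y"] = w.loc["Y", "X"] = 0.5
        out = centrality.node_centrality(w)
        assert out.loc["Z", "strength"] == 0.0
        assert out.loc["Z", "betweenness"] == 0.0
        assert out.loc["Z", "closeness"] == 0.0

    def test_two_edge_path_hand_computed(self):
        w = pd.DataFrame(np.zeros((3, 3)), index=list("ABC"),
                         columns=list("ABC"))
        w.loc["A", "B"] = w.loc["B", "A"] = 0.5
        w.loc["B", "C"] = w.loc["C", "B"] = 0.5
        out = centrality.node_centrality(w)
        assert out.loc["B", "closeness"] == pytest.approx(0.25)
        assert out.loc["B", "betweenness"] == pytest.approx(1.0)
        assert out.loc["A", "betweenness"] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_exhaustive_path_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = 5
        w = rng.uniform(-0.6, 0.6, size=(p, p))
        w = np.triu(w, 1)
        w[np.abs(w) < 0.15] = 0.0  # sparsify
        w = w + w.T
        frame = pd.DataFrame(w, index=list("ABCDE"), columns=list("ABCDE"))
        out = centrality.node_centrality(frame)
        s, c, b, e = oracle_node_centrality(w)
        np.testing.assert_allclose(out["strength"], s, atol=1e-12)
        np.testing.assert_allclose(out["closeness"], c, atol=1e-10)
        np.testing.assert_allclose(out["betweenness"], b, atol=1e-8)
        np.testing.assert_allclose(out["expected_influence_1"], e,
                                   atol=1e-12)

    def test_scaling_weights_scales_strength_keeps_betweenness(self):
        rng = np.random.default_rng(4)
        w = rng.uniform(-0.5, 0.5, size=(5, 5))
        w = np.triu(w, 1) + np.triu(w, 1).T
        frame = pd.DataFrame(w, index=list("ABCDE"), columns=list("ABCDE"))
        base = centrality.node_centrality(frame)
        scaled = centrality.node_centrality(frame * 3.0)
        np.testing.assert_allclose(scaled["strength"],
                                   3.0 * base["strength"])
        np.testing.assert_allclose(scaled["expected_influence_1"],
                                   3.0 * base["expected_influence_1"])
        np.testing.assert_allclose(scaled["betweenness"],
                                   base["betweenness"])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        w = rng.uniform(-0.5, 0.5, size=(5, 5))
        w = np.triu(w, 1) + np.triu(w, 1).T
        labels = list("ABCDE")
        frame = pd.DataFrame(w, index=labels, columns=labels)
        perm = [3, 1, 4, 0, 2]
        permuted = frame.iloc[perm, perm]
        out = centrality.node_centrality(frame)
        out_p = centrality.node_centrality(permuted)
        pd.testing.assert_frame_equal(out.loc[out_p.index], out_p)


# ---------------------------------------------------------------------------
# Bridge centrality
# ---------------------------------------------------------------------------

class TestBridgeCentrality:
    def test_bridge_strength_counts_only_cross_community_edges(self):
        w = pd.DataFrame(np.zeros((3, 3)), index=list("XYZ"),
                         columns=list("XYZ"))
        w.loc["X", "Y"] = w.loc["Y", "X"] = 0.4   # within community 1
        w.loc["X", "Z"] = w.loc["Z", "X"] = 0.2   # cross
        comm = {"X": "c1", "Y": "c1", "Z": "c2"}
        out = centrality.bridge_centrality(w, comm)
        assert out.loc["X", "bridge_strength"] == pytest.approx(0.2)

    def test_bridge_ei1_is_signed_sum(self):
        w = pd.DataFrame(np.zeros((3, 3)), index=list("XYZ"),
                         columns=list("XYZ"))
        w.loc["X", "Y"] = w.loc["Y", "X"] = 0.2    # cross
        w.loc["X", "Z"] = w.loc["Z", "X"] = -0.1   # cross
        comm = {"X": "c1", "Y": "c2", "Z": "c2"}
        out = centrality.bridge_centrality(w, comm)
        assert out.loc["X", "bridge_expected_influence_1"] == \
            pytest.approx(0.1)
        assert out.loc["X", "bridge_strength"] == pytest.approx(0.3)

    def test_matches_exhaustive_path_oracle_on_toy_graph(self, toy_weights):
        frame, communities = toy_weights
        out = centrality.bridge_centrality(frame, communities)
        comm = np.array([communities[v] for v in frame.columns])
        s, c, b, e = oracle_bridge_centrality(frame.to_numpy(), comm)
        np.testing.assert_allclose(out["bridge_strength"], s, atol=1e-12)
        np.testing.assert_allclose(out["bridge_closeness"], c, atol=1e-10)
        np.testing.assert_allclose(out["bridge_betweenness"], b, atol=1e-8)
        np.testing.assert_allclose(out["bridge_expected_influence_1"], e,
                                   atol=1e-12)

    def test_single_community_zeroes_bridge_strength(self, toy_weights):
        frame, _ = toy_weights
        comm = {v: "all" for v in frame.columns}
        out = centrality.bridge_centrality(frame, comm)
        assert (out["bridge_strength"] == 0.0).all()
        assert (out["bridge_expected_influence_1"] == 0.0).all()

    def test_unassigned_node_is_error(self, toy_weights):
        frame, communities = toy_weights
        partial = {k: v for k, v in communities.items() if k != "D"}
        with pytest.raises(ConfigError, match="D"):
            centrality.bridge_centrality(frame, partial)

    def test_bridge_strength_bounded_by_strength(self, toy_weights):
        frame, communities = toy_weights
        node = centrality.node_centrality(frame)
        bridge = centrality.bridge_centrality(frame, communities)
        assert (bridge["bridge_strength"]
                <= node["strength"] + 1e-12).all()
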