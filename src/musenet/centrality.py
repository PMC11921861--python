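"""Node and bridge centrality on signed weighted networks.

Conventions (standard in the psychometric-network literature):

* strength(i) = sum_j |w_ij|; expected influence (one-step) is the signed
  sum, so |EI1| <= strength always.
* Shortest-path indices use the edge distance d_ij = 1 / |w_ij|.  Closeness
  is the inverse of the total shortest-path distance to the reachable nodes;
  nodes with no reachable neighbours get closeness 0, and unreachable pairs
  simply contribute nothing to the sum.
* Betweenness uses Brandes accounting: when several equal-length shortest
  paths exist (path lengths compared at 1e-10 tolerance) the credit is
  split fractionally.  Each unordered pair is counted once.
* Bridge indices are the same four quantities restricted to edges or node
  pairs crossing community boundaries; bridge closeness is the inverse of
  the mean distance to the nodes outside the node's own community.

The default community partition for the study's workflow assigns each node
to its instrument: the music-use node alone, the three self-efficacy
dimensions, the three alexithymia facets, and anxiety + depression.
"""

from __future__ import annotations

import heapq
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .ggm import EDGE_EPS, PartialCorrelationNetwork

#: Tolerance at which two floating-point path lengths count as tied.
PATH_TIE_TOL = 1e-10

#: Instrument-membership communities for the study node sets.
DEFAULT_COMMUNITIES: dict[str, str] = {
    "HMU": "music", "UHMU": "music",
    "POS": "self-efficacy", "DES": "self-efficacy", "ANG": "self-efficacy",
    "DIF": "alexithymia", "DDF": "alexithymia", "EOT": "alexithymia",
    "Anx": "distress", "Dep": "distress",
}

CENTRALITY_INDICES = ("strength", "closeness", "betweenness",
                      "expected_influence_1")
BRIDGE_INDICES = ("bridge_strength", "bridge_closeness",
                  "bridge_betweenness", "bridge_expected_influence_1")


def _weight_matrix(network) -> tuple[np.ndarray, list[str]]:
    if isinstance(network, PartialCorrelationNetwork):
        return network.weights, list(network.labels)
    if isinstance(network, pd.DataFrame):
        return network.to_numpy(dtype=float), [str(c) for c in network.columns]
    raise ConfigError("network must be a PartialCorrelationNetwork or a "
                      "labeled symmetric DataFrame")


def _dijkstra(dist_adj: list[list[tuple[int, float]]], source: int,
              p: int) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Single-source shortest paths with tie-tolerant path counting.

    Returns distances, number-of-shortest-paths sigma, and the settled
    order (for Brandes back-propagation).
    """
    dist = np.full(p, np.inf)
    sigma = np.zeros(p)
    dist[source] = 0.0
    sigma[source] = 1.0
    order: list[int] = []
    seen = np.zeros(p, dtype=bool)
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if seen[u]:
            continue
        seen[u] = True
        order.append(u)
        for v, w in dist_adj[u]:
            nd = d + w
            if nd < dist[v] - PATH_TIE_TOL:
                dist[v] = nd
                sigma[v] = sigma[u]
                heapq.heappush(heap, (nd, v))
            elif abs(nd - dist[v]) <= PATH_TIE_TOL and not seen[v]:
                sigma[v] += sigma[u]
    return dist, sigma, order


def _adjacency(weights: np.ndarray) -> list[list[tuple[int, float]]]:
    p = weights.shape[0]
    adj: list[list[tuple[int, float]]] = [[] for _ in range(p)]
    for i in range(p):
        for j in range(p):
            if i != j and abs(weights[i, j]) > EDGE_EPS:
                adj[i].append((j, 1.0 / abs(weights[i, j])))
    return adj


def node_centrality(network, zscored: bool = False) -> pd.DataFrame:
    """Strength, closeness, betweenness and one-step expected influence.

    With ``zscored=True`` the columns are z-standardized across nodes
    (constant columns map to 0), matching how centrality profiles are
    usually plotted.
    """
    w, labels = _weight_matrix(network)
    p = len(labels)
    absw = np.abs(w)
    np.fill_diagonal(absw, 0.0)
    strength = absw.sum(axis=1)
    ei1 = (w - np.diag(np.diag(w))).sum(axis=1)

    adj = _adjacency(w)
    closeness = np.zeros(p)
    betweenness = np.zeros(p)
    for s in range(p):
        dist, sigma, order = _dijkstra(adj, s, p)
        reach = np.isfinite(dist) & (np.arange(p) != s)
        if reach.any():
            closeness[s] = 1.0 / dist[reach].sum()
        # Brandes dependency accumulation over the settled order, reversed
        delta = np.zeros(p)
        for v in reversed(order):
            for u, wd in adj[v]:
                # u is a predecessor of v if it lies on a shortest path
                if abs(dist[u] + wd - dist[v]) <= PATH_TIE_TOL:
                    delta[u] += sigma[u] / sigma[v] * (1.0 + delta[v])
            if v != s:
                betweenness[v] += delta[v]
    betweenness /= 2.0  # each unordered pair was counted from both ends

    out = pd.DataFrame(
        {"strength": strength, "closeness": closeness,
         "betweenness": betweenness, "expected_influence_1": ei1},
        index=labels,
    )
    return zscore_columns(out) if zscored else out


def zscore_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Z-standardize each column across nodes; constant columns become 0."""
    sd = table.std(ddof=1).replace(0.0, np.nan)
    z = (table - table.mean()) / sd
    return z.fillna(0.0)


def bridge_centrality(network, communities: Mapping[str, str] | None = None,
                      zscored: bool = False) -> pd.DataFrame:
    """The four bridge centrality indices under a community partition.

    ``communities`` maps every node label to a community label; the default
    is instrument membership for the study's node names.
    """
    w, labels = _weight_matrix(network)
    p = len(labels)
    comm_map = DEFAULT_COMMUNITIES if communities is None else communities
    missing = [v for v in labels if v not in comm_map]
    if missing:
        raise ConfigError(f"nodes without a community assignment: {missing}")
    comm = np.array([comm_map[v] for v in labels])

    cross = comm[:, None] != comm[None, :]
    absw = np.abs(w)
    np.fill_diagonal(absw, 0.0)
    signed = w - np.diag(np.diag(w))
    b_strength = (absw * cross).sum(axis=1)
    b_ei1 = (signed * cross).sum(axis=1)

    adj = _adjacency(w)
    dist = np.empty((p, p))
    sigma = np.empty((p, p))
    for s in range(p):
        dist[s], sigma[s], _ = _dijkstra(adj, s, p)

    # bridge closeness: inverse mean distance to reachable out-community nodes
    b_closeness = np.zeros(p)
    for i in range(p):
        outside = cross[i] & np.isfinite(dist[i])
        if outside.any():
            b_closeness[i] = 1.0 / dist[i][outside].mean()

    # bridge betweenness: fractional count of shortest cross-community paths
    # through each interior node
    b_betweenness = np.zeros(p)
    for u in range(p):
        for v in range(u + 1, p):
            if not cross[u, v] or not np.isfinite(dist[u, v]):
                continue
            for i in range(p):
                if i in (u, v) or not np.isfinite(dist[u, i]):
                    continue
                if abs(dist[u, i] + dist[i, v] - dist[u, v]) <= PATH_TIE_TOL:
                    b_betweenness[i] += sigma[u, i] * sigma[v, i] / sigma[u, v]

    out = pd.DataFrame(
        {"bridge_strength": b_strength, "bridge_closeness": b_closeness,
         "bridge_betweenness": b_betweenness,
         "bridge_expected_influence_1": b_ei1},
        index=labels,
    )
    return zscore_columns(out) if zscored else out
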