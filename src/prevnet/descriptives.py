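"""Network descriptives: strength centrality, global strength, average
shortest path length, and consensus community detection.

Consensus communities follow an iterated procedure: the walktrap
algorithm (short-random-walk agglomerative modularity clustering) is run
on bootstrap-re-estimated networks many times; node pairs that land in
the same community in more than a threshold fraction of iterations form
the consensus clusters.  Walktrap itself is deterministic on a fixed
graph, so the iteration operates on resampled data — the only reading
under which a co-membership frequency criterion is informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .estimation import MGMNetwork, GGMNetwork, estimate_mgm
from .roster import NodeSpec

__all__ = [
    "strength",
    "global_strength",
    "average_shortest_path_length",
    "walktrap_membership",
    "consensus_communities",
    "CommunityConsensus",
]

log = logging.getLogger(__name__)

Network = MGMNetwork | GGMNetwork


def _weights_nodes(network) -> tuple[np.ndarray, list[str]]:
    if isinstance(network, np.ndarray):
        w = network
        nodes = [f"x{i}" for i in range(w.shape[0])]
    else:
        w, nodes = np.asarray(network.weights), list(network.nodes)
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("weights must be symmetric")
    return w, nodes


def strength(network: Network | np.ndarray, standardize: bool = False) -> pd.DataFrame:
    """Node strength: sum of absolute incident edge weights.

    With ``standardize=True`` a z-scored column is added (display option;
    raw strength is the default reporting scale)."""
    w, nodes = _weights_nodes(network)
    s = np.abs(w).sum(axis=1)
    out = pd.DataFrame({"node": nodes, "strength": s})
    if standardize:
        sd = s.std(ddof=0)
        out["strength_z"] = (s - s.mean()) / sd if sd > 0 else 0.0
    return out


def global_strength(network: Network | np.ndarray) -> float:
    """Sum of absolute edge weights over unordered node pairs."""
    w, _ = _weights_nodes(network)
    return float(np.abs(np.triu(w, 1)).sum())


def average_shortest_path_length(network: Network | np.ndarray) -> tuple[float, int]:
    """Average Dijkstra distance over connected ordered pairs, edge
    distances 1/|w|.  Returns (ASPL, number of disconnected ordered pairs)."""
    w, nodes = _weights_nodes(network)
    p = len(nodes)
    g = nx.Graph()
    g.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            if w[i, j] != 0.0:
                g.add_edge(i, j, dist=1.0 / abs(w[i, j]))
    if g.number_of_edges() == 0:
        raise ValueError("network has no edges")
    total, n_pairs, disconnected = 0.0, 0, 0
    for src, dists in nx.all_pairs_dijkstra_path_length(g, weight="dist"):
        for dst in range(p):
            if dst == src:
                continue
            if dst in dists:
                total += dists[dst]
                n_pairs += 1
            else:
                disconnected += 1
    if n_pairs == 0:
        raise ValueError("network is fully disconnected")
    return total / n_pairs, disconnected


def walktrap_membership(weights: np.ndarray, steps: int = 4) -> np.ndarray:
    """Walktrap community membership on absolute edge weights.

    Runs on |w| because random-walk transition probabilities require
    non-negative weights; the sign structure is reported separately by the
    estimation stage.  An empty graph yields all-singleton membership.
    """
    w = np.abs(np.asarray(weights, dtype=float))
    p = w.shape[0]
    ii, jj = np.nonzero(np.triu(w, 1))
    if ii.size == 0:
        return np.arange(p)
    g = ig.Graph(n=p, edges=list(zip(ii.tolist(), jj.tolist())))
    g.es["weight"] = w[ii, jj].tolist()
    dendro = g.community_walktrap(weights="weight", steps=steps)
    return np.asarray(dendro.as_clustering().membership)


@dataclass
class CommunityConsensus:
    nodes: list[str]
    iterations: int
    threshold: float
    co_membership: np.ndarray
    consensus_clusters: list[list[str]]

    def cluster_of(self, code: str) -> list[str]:
        for cl in self.consensus_clusters:
            if code in cl:
                return cl
        raise KeyError(code)


def consensus_communities(
    wave_data: pd.DataFrame,
    roster: list[NodeSpec],
    iterations: int = 1000,
    threshold: float = 0.9,
    seed: int = 0,
    estimator: Callable[[pd.DataFrame], Network] | None = None,
    walktrap_steps: int = 4,
) -> CommunityConsensus:
    """Bootstrap-iterated walktrap consensus clustering.

    Per iteration, participants are resampled with replacement, the network
    is re-estimated, and walktrap is run on the absolute weights; pairwise
    co-membership frequencies are accumulated.  Consensus clusters are the
    connected components of the graph keeping node pairs whose co-membership
    frequency exceeds ``threshold``; unattached nodes become singletons.
    """
    if iterations < 100:
        raise ValueError("iterations must be >= 100")
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    if estimator is None:
        estimator = lambda df: estimate_mgm(df, roster)  # noqa: E731

    rng = np.random.default_rng(seed)
    n = len(wave_data)
    first = estimator(wave_data)
    nodes = list(first.nodes)
    p = len(nodes)
    co = np.zeros((p, p))
    done = 0
    while done < iterations:
        idx = rng.integers(0, n, size=n)
        resample = wave_data.iloc[idx]
        try:
            net = estimator(resample)
            member = walktrap_membership(net.weights, steps=walktrap_steps)
        except ValueError:
            # degenerate resample (e.g. constant column): all singletons
            member = np.arange(p)
        co += member[:, None] == member[None, :]
        done += 1
    co /= iterations
    np.fill_diagonal(co, 1.0)

    keep = co > threshold
    np.fill_diagonal(keep, False)
    g = nx.from_numpy_array(keep.astype(int))
    clusters = [sorted(nodes[i] for i in comp) for comp in nx.connected_components(g)]
    clusters.sort(key=lambda c: (-len(c), c))
    return CommunityConsensus(
        nodes=nodes,
        iterations=iterations,
        threshold=threshold,
        co_membership=co,
        consensus_clusters=clusters,
    )
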