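"""Random-network null models.

Two ensembles are provided: Erdos-Renyi G(n, M) graphs matched on node and
edge counts (the null for the small-world comparison), and degree-preserving
randomizations produced by repeated double edge swaps (the null for rich-club
normalization). A double edge swap replaces edges (u, v), (x, y) with
(u, x), (v, y), which leaves every node degree untouched; swaps that would
create a self-loop or a duplicate edge are rejected, so members remain simple
graphs with exactly the input degree sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class NullEnsembleConfig:
    """Configuration for a random-network ensemble.

    ``swaps_per_edge`` sets the rewiring intensity for the degree-preserving
    kind: each member receives ``swaps_per_edge * |E|`` accepted swaps
    (default 10, a common mixing heuristic). ``preserve_connectivity``
    additionally rejects swaps that disconnect the graph (off by default:
    rich-club counting does not require connectivity).
    """

    kind: str = "degree_preserving"          # or "erdos_renyi"
    n_networks: int = 1000
    swaps_per_edge: float = 10.0
    preserve_connectivity: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("degree_preserving", "erdos_renyi"):
            raise ValueError(f"unknown ensemble kind {self.kind!r}")
        if self.n_networks < 1:
            raise ValueError("n_networks must be >= 1")
        if self.swaps_per_edge <= 0:
            raise ValueError("swaps_per_edge must be > 0")


def double_edge_swap(G: nx.Graph, n_swaps: int,
                     seed: int | np.random.Generator = 0,
                     max_tries: int | None = None,
                     preserve_connectivity: bool = False) -> nx.Graph:
    """Return a degree-preserving randomization of ``G``.

    Performs ``n_swaps`` accepted double edge swaps, rejecting any candidate
    that would create a self-loop or duplicate edge (and, when
    ``preserve_connectivity`` is set, any accepted swap that disconnects the
    graph — checked and rolled back after the fact). If fewer than
    ``n_swaps`` swaps are accepted within ``max_tries`` attempts (default
    ``100 * n_swaps``) the best-effort result is returned with a warning.
    """
    if G.number_of_edges() < 2:
        raise ValueError("need at least 2 edges to swap")
    rng = np.random.default_rng(seed)
    if max_tries is None:
        max_tries = 100 * max(n_swaps, 1)

    nodes = list(G.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in G.edges()]
    adj: list[set[int]] = [set() for _ in nodes]
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    m = len(edges)
    accepted = 0
    tries = 0
    # pre-drawn randomness in blocks keeps the Python loop tight
    block = 8192
    buf_idx = rng.integers(0, m, size=(0, 2))
    buf_flip = rng.random(0)
    pos = block
    while accepted < n_swaps and tries < max_tries:
        if pos >= len(buf_flip):
            buf_idx = rng.integers(0, m, size=(block, 2))
            buf_flip = rng.random(block)
            pos = 0
        i, j = buf_idx[pos]
        flip = buf_flip[pos] < 0.5
        pos += 1
        tries += 1
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if flip:
            x, y = y, x
        # propose (u, v), (x, y) -> (u, x), (v, y)
        if u == x or v == y or x in adj[u] or y in adj[v]:
            continue
        adj[u].discard(v); adj[v].discard(u)
        adj[x].discard(y); adj[y].discard(x)
        adj[u].add(x); adj[x].add(u)
        adj[v].add(y); adj[y].add(v)
        edges[i] = (u, x)
        edges[j] = (v, y)
        accepted += 1
        if preserve_connectivity:
            H = nx.Graph()
            H.add_nodes_from(range(len(nodes)))
            H.add_edges_from(edges)
            if not nx.is_connected(H):
                # roll back
                adj[u].discard(x); adj[x].discard(u)
                adj[v].discard(y); adj[y].discard(v)
                adj[u].add(v); adj[v].add(u)
                adj[x].add(y); adj[y].add(x)
                edges[i] = (u, v)
                edges[j] = (x, y)
                accepted -= 1
    if accepted < n_swaps:
        logger.warning("double_edge_swap: only %d of %d swaps accepted "
                       "after %d attempts", accepted, n_swaps, tries)
    H = nx.Graph()
    H.add_nodes_from(nodes)
    H.add_edges_from((nodes[a], nodes[b]) for a, b in edges)
    H.graph["accepted_swaps"] = accepted
    return H


def generate_ensemble(G: nx.Graph, config: NullEnsembleConfig) -> list[nx.Graph]:
    """Generate ``config.n_networks`` independent random networks.

    Each member draws from an independent random stream spawned from the
    master seed, so ensembles are a pure function of (G, config) and members
    do not depend on how many preceded them.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_networks)
    members: list[nx.Graph] = []
    if config.kind == "degree_preserving":
        n_swaps = int(round(config.swaps_per_edge * G.number_of_edges()))
        for child in children:
            members.append(double_edge_swap(
                G, n_swaps, seed=np.random.default_rng(child),
                preserve_connectivity=config.preserve_connectivity))
    else:
        n, m = G.number_of_nodes(), G.number_of_edges()
        for child in children:
            rng = np.random.default_rng(child)
            members.append(nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31 - 1))))
    return members
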