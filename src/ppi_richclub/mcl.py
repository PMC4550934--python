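"""Markov clustering (MCL) of an interaction network into modules.

MCL simulates random-walk flow on the graph: a column-stochastic transition
matrix (adjacency plus self-loops) is alternately *expanded* (matrix power,
spreading flow) and *inflated* (entrywise power followed by column
renormalization, sharpening flow) until the matrix reaches a doubly
idempotent limit. Clusters are read off the limit matrix as attractor
systems: rows with mass on their own diagonal attract the columns (nodes)
that carry flow toward them. The procedure is fully deterministic.

The partition is then filtered by module size (the downstream analysis keeps
modules of five or more proteins) and abstracted into a module meta-network
whose edge weights count inter-module interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ModulePartition:
    """Node -> module assignment plus size bookkeeping.

    ``assignment`` maps every node to a raw module id (1-based). After
    :func:`filter_modules`, ``kept`` maps raw ids of modules with size >=
    min_size to their size rank (1 = largest), and ``small`` lists raw ids
    flagged "unassigned-small".
    """

    assignment: dict = field(repr=False)
    module_sizes: dict = field(default_factory=dict)
    kept: dict = field(default_factory=dict)
    small: list = field(default_factory=list)
    min_size: int | None = None
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self):
        if not self.module_sizes:
            sizes: dict[int, int] = {}
            for m in self.assignment.values():
                sizes[m] = sizes.get(m, 0) + 1
            self.module_sizes = sizes

    def members(self, module_id: int) -> set:
        return {v for v, m in self.assignment.items() if m == module_id}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted((str(v), m, self.kept.get(m, 0),
                       "kept" if m in self.kept else "unassigned-small")
                      for v, m in self.assignment.items())
        return pd.DataFrame(rows, columns=["node", "module", "size_rank", "status"])


@dataclass
class MetaNetwork:
    """Module-level abstraction of the network.

    Nodes are kept module ids; the weight w(i, j) counts edges between
    members of modules i and j. ``module_degree`` is the weighted degree
    (sum of w over partners); ``intra_edges`` counts within-module edges and
    ``external_edges`` counts edges touching nodes of non-kept modules, so
    that intra + inter + external equals |E| of the underlying graph.
    """

    graph: nx.Graph
    module_degree: dict
    intra_edges: dict
    external_edges: int

    def ranking(self) -> list[tuple[int, float]]:
        return sorted(self.module_degree.items(), key=lambda kv: (-kv[1], kv[0]))


def _normalize_columns(M: np.ndarray) -> np.ndarray:
    s = M.sum(axis=0)
    s[s == 0] = 1.0
    return M / s


def mcl_cluster(G: nx.Graph, inflation: float = 2.0, expansion: int = 2,
                max_iter: int = 100, tol: float = 1e-6,
                prune_threshold: float = 1e-5,
                weighted: bool = False) -> ModulePartition:
    """Cluster ``G`` with Markov clustering.

    Parameters
    ----------
    inflation : float
        Entrywise power applied each iteration; larger values give finer
        clusters. Must be > 1.
    expansion : int
        Matrix power applied each iteration (>= 2).
    prune_threshold : float
        Entries below this are zeroed (then columns renormalized) to keep the
        matrix sparse in effect; purely a numerical economy.
    weighted : bool
        Use edge ``weight`` attributes instead of binary adjacency.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if expansion < 2:
        raise ValueError("expansion must be >= 2")
    nodes = sorted(G.nodes(), key=str)
    A = nx.to_numpy_array(G, nodelist=nodes,
                          weight="weight" if weighted else None)
    np.fill_diagonal(A, 1.0)  # self-loops damp parity effects of the walk
    M = _normalize_columns(A)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        last = M
        M = np.linalg.matrix_power(M, expansion)
        M = _normalize_columns(np.power(M, inflation))
        M[M < prune_threshold] = 0.0
        M = _normalize_columns(M)
        if np.max(np.abs(M - last)) < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations; "
                       "clustering the final matrix", max_iter)

    assignment = _read_clusters(M, nodes)
    return ModulePartition(assignment=assignment, converged=converged,
                           n_iterations=it)


def _read_clusters(M: np.ndarray, nodes: list) -> dict:
    """Read attractor systems off the (near-)limit MCL matrix.

    Attractors are rows with positive diagonal mass. Attractors whose rows
    share a supporting column belong to one attractor system. Each node joins
    the system holding its largest column entry (ties -> lowest module id).
    """
    n = M.shape[0]
    eps = 1e-12
    attractors = [i for i in range(n) if M[i, i] > eps]
    if not attractors:  # pathological; treat max-row entries as attractors
        attractors = sorted(set(int(np.argmax(M[:, j])) for j in range(n)))
    # union attractors that co-occur in any column
    parent = {a: a for a in attractors}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    att_set = set(attractors)
    for j in range(n):
        support = [i for i in attractors if M[i, j] > eps]
        for a, b in zip(support, support[1:]):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    roots = sorted({find(a) for a in attractors})
    system_id = {}
    for a in attractors:
        system_id[a] = roots.index(find(a)) + 1

    assignment = {}
    for j, v in enumerate(nodes):
        support = [(M[i, j], -i) for i in attractors if M[i, j] > eps]
        if support:
            best = max(support)
            assignment[v] = system_id[-best[1]]
        else:
            # no flow toward any attractor (isolated numerical corner):
            # fall back to the strongest row overall
            i = int(np.argmax(M[:, j])) if M[:, j].max() > 0 else j
            assignment[v] = system_id.get(i, len(roots) + 1 + j)
            if i not in att_set:
                logger.warning("node %r has no attractor support; singleton", v)
    # renumber raw ids consecutively from 1 in first-appearance order of nodes
    remap = {}
    for v in nodes:
        m = assignment[v]
        if m not in remap:
            remap[m] = len(remap) + 1
    return {v: remap[assignment[v]] for v in nodes}


def filter_modules(partition: ModulePartition, min_size: int = 5) -> ModulePartition:
    """Flag modules below ``min_size`` and rank the kept ones by size.

    Kept modules are renumbered by descending size (ties broken by raw id);
    nodes keep their raw module id in ``assignment``.
    """
    sizes = partition.module_sizes
    kept_ids = sorted((m for m, s in sizes.items() if s >= min_size),
                      key=lambda m: (-sizes[m], m))
    kept = {m: rank for rank, m in enumerate(kept_ids, start=1)}
    small = sorted(m for m in sizes if m not in kept)
    return ModulePartition(assignment=dict(partition.assignment),
                           module_sizes=dict(sizes), kept=kept, small=small,
                           min_size=min_size, converged=partition.converged,
                           n_iterations=partition.n_iterations)


def meta_network(G: nx.Graph, partition: ModulePartition) -> MetaNetwork:
    """Collapse the network onto its kept modules.

    Edge weight w(i, j) counts interactions between members of kept modules
    i and j (raw ids); ``module_degree`` sums those weights per module. Edges
    inside one module are tallied in ``intra_edges``; edges touching a node
    of a non-kept module are tallied in ``external_edges``. The three groups
    partition the edge set exactly.
    """
    kept = partition.kept if partition.kept else {
        m: r for r, m in enumerate(sorted(partition.module_sizes), start=1)}
    if not kept:
        raise ValueError("no kept modules")
    meta = nx.Graph()
    meta.add_nodes_from(sorted(kept))
    intra = {m: 0 for m in kept}
    external = 0
    for a, b in G.edges():
        ma, mb = partition.assignment[a], partition.assignment[b]
        if ma not in kept or mb not in kept:
            external += 1
        elif ma == mb:
            intra[ma] += 1
        else:
            w = meta[ma][mb]["weight"] + 1 if meta.has_edge(ma, mb) else 1
            meta.add_edge(ma, mb, weight=w)
    degree = {m: 0.0 for m in kept}
    for m in kept:
        degree[m] = float(sum(d["weight"] for _, _, d in meta.edges(m, data=True)))
    return MetaNetwork(graph=meta, module_degree=degree,
                       intra_edges=intra, external_edges=external)
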