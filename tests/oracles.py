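"""Independent reference implementations used only to check the package.

Each oracle is written from the bare definition of the quantity it checks —
brute-force subgraph counting for the rich-club coefficient, a literal
unpruned matrix iteration for MCL, exact-integer hypergeometric enumeration
for Fisher's test — and shares no code path with the implementation.
"""

from __future__ import annotations

from math import comb

import networkx as nx
import numpy as np


def brute_force_phi(G: nx.Graph) -> dict[int, float]:
    """phi(k) by literally building the degree->k subgraph at every k."""
    degrees = dict(G.degree())
    out = {}
    for k in range(max(degrees.values())):
        members = [v for v, d in degrees.items() if d > k]
        if len(members) < 2:
            continue
        E = G.subgraph(members).number_of_edges()
        out[k] = 2.0 * E / (len(members) * (len(members) - 1))
    return out


def mcl_oracle(G: nx.Graph, inflation: float = 2.0, expansion: int = 2,
               max_iter: int = 200, tol: float = 1e-6) -> dict:
    """Literal MCL: dense matrix iteration, no pruning.

    Clusters are read as connected components of the support of the limit
    matrix (an i~j link whenever M[i, j] > eps).
    """
    nodes = sorted(G.nodes(), key=str)
    n = len(nodes)
    A = np.zeros((n, n))
    pos = {v: i for i, v in enumerate(nodes)}
    for a, b in G.edges():
        A[pos[a], pos[b]] = A[pos[b], pos[a]] = 1.0
    for i in range(n):
        A[i, i] = 1.0
    M = A / A.sum(axis=0)
    for _ in range(max_iter):
        last = M.copy()
        M = np.linalg.matrix_power(M, expansion)
        M = M ** inflation
        M = M / M.sum(axis=0)
        if np.abs(M - last).max() < tol:
            break
    S = nx.Graph()
    S.add_nodes_from(range(n))
    eps = 1e-8
    for i in range(n):
        for j in range(n):
            if M[i, j] > eps:
                S.add_edge(i, j)
    comp = {v: ci for ci, cc in enumerate(nx.connected_components(S))
            for v in cc}
    return {nodes[i]: comp[i] for i in range(n)}


def same_partition(a: dict, b: dict) -> bool:
    """True when two node->label maps induce the same set of blocks."""
    blocks_a: dict = {}
    blocks_b: dict = {}
    for v, lab in a.items():
        blocks_a.setdefault(lab, set()).add(v)
    for v, lab in b.items():
        blocks_b.setdefault(lab, set()).add(v)
    key = lambda bl: sorted(map(str, bl))  # noqa: E731
    return sorted(map(key, blocks_a.values())) == sorted(map(key, blocks_b.values()))


def fisher_two_sided_oracle(r1: int, r2: int, c1: int) -> dict[int, float]:
    """Two-sided Fisher p for every observed ``a`` at fixed margins.

    Enumerates all tables with margins (r1, r2) x (c1, n - c1) and sums the
    exact-integer hypergeometric numerators of tables no more likely than the
    observed one (comparison is exact, on integers).
    """
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [comb(c1, a) * comb(n - c1, r1 - a) for a in range(lo, hi + 1)]
    total = comb(n, r1)
    out = {}
    for i, a in enumerate(range(lo, hi + 1)):
        out[a] = sum(x for x in nums if x <= nums[i]) / total
    return out


def adjusted_rand_index(labels_a: list, labels_b: list) -> float:
    """ARI from the contingency table (pair-counting form)."""
    from collections import Counter
    n = len(labels_a)
    cont = Counter(zip(labels_a, labels_b))
    a_sizes = Counter(labels_a)
    b_sizes = Counter(labels_b)
    sum_comb = sum(comb(c, 2) for c in cont.values())
    sum_a = sum(comb(c, 2) for c in a_sizes.values())
    sum_b = sum(comb(c, 2) for c in b_sizes.values())
    exp = sum_a * sum_b / comb(n, 2)
    max_idx = (sum_a + sum_b) / 2
    if max_idx == exp:
        return 1.0
    return (sum_comb - exp) / (max_idx - exp)
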