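"""Median-joining haplotype networks (Bandelt et al. 1999 style).

The minimum spanning network (MSN) over a haplotype set is the union of
all minimum spanning trees: a pair is linked iff its Hamming distance
does not exceed the minimax path weight between the two nodes (plus an
integer relaxation epsilon).  Median joining then repeatedly proposes
the consensus (majority per site) of connected node triples and keeps
any median vector that shortens the spanning length, pruning inferred
vectors that stop paying for themselves.  Processing order is fixed
(lexicographic) so the result is deterministic.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

__all__ = ["median_joining_network", "mst_length"]

MAX_HAPLOTYPES = 64


def _distance_matrix(nodes: list[tuple[int, ...]]) -> np.ndarray:
    arr = np.array(nodes, dtype=np.int16)
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=2)


def mst_length(nodes: list[tuple[int, ...]]) -> int:
    """Total weight of a minimum spanning tree on Hamming distances."""
    if len(nodes) < 2:
        return 0
    d = _distance_matrix(nodes)
    return int(round(minimum_spanning_tree(d).sum()))


def _mst_edges(d: np.ndarray) -> list[tuple[int, int, int]]:
    t = minimum_spanning_tree(d).tocoo()
    return [(int(i), int(j), int(v)) for i, j, v in zip(t.row, t.col, t.data)]


def _minimax(d: np.ndarray) -> np.ndarray:
    """Minimax path weight between all pairs, via the MST."""
    n = d.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j, w in _mst_edges(d):
        g.add_edge(i, j, weight=w)
    mm = np.zeros((n, n), dtype=np.int64)
    for src in range(n):
        # DFS from src tracking the max edge weight seen on the path
        stack = [(src, 0)]
        seen = {src}
        while stack:
            u, best = stack.pop()
            for v in g.neighbors(u):
                if v not in seen:
                    seen.add(v)
                    w = max(best, g.edges[u, v]["weight"])
                    mm[src, v] = w
                    stack.append((v, w))
    return mm


def _msn_edges(nodes: list[tuple[int, ...]], epsilon: int) -> list[tuple[int, int, int]]:
    if len(nodes) < 2:
        return []
    d = _distance_matrix(nodes)
    mm = _minimax(d)
    edges = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if d[i, j] <= mm[i, j] + epsilon:
                edges.append((i, j, int(d[i, j])))
    return edges


def _median(a, b, c) -> tuple[int, ...]:
    out = []
    for x, y, z in zip(a, b, c):
        votes = sorted((x, y, z))
        out.append(votes[1])  # majority (or middle state for multi-state)
    return tuple(out)


def median_joining_network(
    haplotypes: list[str] | list[tuple[int, ...]],
    epsilon: int = 0,
    frequencies: dict[str, float] | None = None,
    labels: dict[str, str] | None = None,
) -> nx.Graph:
    """Median-joining network of up to 64 distinct haplotypes.

    Nodes carry ``sequence`` (the haplotype string), ``observed``
    (False for inferred median vectors), and optional ``frequency`` /
    ``label`` attributes; edges carry ``weight`` (number of differing
    sites) and ``sites`` (their indices).
    """
    seqs: list[tuple[int, ...]] = []
    for h in haplotypes:
        t = tuple(int(c) for c in h)
        if t not in seqs:
            seqs.append(t)
    if not seqs:
        raise ValueError("no haplotypes")
    if len(seqs) > MAX_HAPLOTYPES:
        raise ValueError(f"more than {MAX_HAPLOTYPES} distinct haplotypes")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("haplotypes must have equal length")
    observed = sorted(seqs)
    nodes = list(observed)

    # -- add medians of connected triples while they shorten the network
    while True:
        edges = _msn_edges(nodes, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for i, j, _ in edges:
            adj[i].add(j)
            adj[j].add(i)
        candidates: set[tuple[int, ...]] = set()
        for v, nbrs in adj.items():
            for a, b in itertools.combinations(sorted(nbrs), 2):
                m = _median(nodes[a], nodes[b], nodes[v])
                if m not in nodes:
                    candidates.add(m)
        base_len = mst_length(nodes)
        best = None
        for m in sorted(candidates):
            delta = base_len - mst_length(nodes + [m])
            if delta > 0 and (best is None or delta > best[0] or (delta == best[0] and m < best[1])):
                best = (delta, m)
        if best is None:
            break
        nodes.append(best[1])

    # -- prune median vectors that no longer shorten the network
    changed = True
    while changed:
        changed = False
        for m in sorted(n for n in nodes if n not in observed):
            rest = [n for n in nodes if n != m]
            if mst_length(rest) <= mst_length(nodes):
                nodes = rest
                changed = True
                break

    g = nx.Graph()
    for n in nodes:
        seq = "".join(map(str, n))
        attrs = {"sequence": seq, "observed": n in observed}
        if frequencies and seq in frequencies:
            attrs["frequency"] = frequencies[seq]
        if labels and seq in labels:
            attrs["label"] = labels[seq]
        g.add_node(seq, **attrs)
    for i, j, w in _msn_edges(nodes, epsilon):
        si = "".join(map(str, nodes[i]))
        sj = "".join(map(str, nodes[j]))
        sites = [k for k, (x, y) in enumerate(zip(nodes[i], nodes[j])) if x != y]
        g.add_edge(si, sj, weight=w, sites=sites)
    return g
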