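"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the package's own graph code: trees are handled
through networkx, distances by BFS, the GCN by explicit per-node loops, and
the scorer by naive counting.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np


def tree_graph(heads: list[int]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(1, len(heads) + 1))
    for i, h in enumerate(heads, start=1):
        if h != 0:
            g.add_edge(i, h)
    return g


def digraph(heads: list[int]) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(range(1, len(heads) + 1))
    for i, h in enumerate(heads, start=1):
        if h != 0:
            g.add_edge(h, i)  # parent -> child
    return g


def oracle_lca(heads: list[int], span1, span2) -> int:
    """Deepest node whose descendant set contains both spans."""
    dg = digraph(heads)
    root = next(i for i, h in enumerate(heads, start=1) if h == 0)
    targets = set(span1) | set(span2)
    depth = nx.shortest_path_length(dg, root)
    best, best_depth = None, -1
    for node in dg.nodes:
        descendants = nx.descendants(dg, node) | {node}
        if targets <= descendants and depth[node] > best_depth:
            best, best_depth = node, depth[node]
    return best


def oracle_path(heads: list[int], span1, span2) -> set[int]:
    g = tree_graph(heads)
    anc = oracle_lca(heads, span1, span2)
    dg = digraph(heads)
    root = next(i for i, h in enumerate(heads, start=1) if h == 0)
    depth = nx.shortest_path_length(dg, root)
    path = {anc} | set(span1) | set(span2)
    for span in (span1, span2):
        top = min(sorted(span), key=lambda v: depth[v])
        path |= set(nx.shortest_path(g, top, anc))
    return path


def oracle_prune(heads: list[int], span1, span2, N) -> set[int]:
    """BFS-distance pruning within the LCA subtree."""
    dg = digraph(heads)
    anc = oracle_lca(heads, span1, span2)
    subtree = nx.descendants(dg, anc) | {anc}
    if N == math.inf:
        return set(subtree)
    g = tree_graph(heads).subgraph(subtree)
    path = oracle_path(heads, span1, span2)
    kept = set(path)
    for node in subtree:
        dist = min(nx.shortest_path_length(g, node, p) for p in path)
        if dist <= N:
            kept.add(node)
    return kept


def oracle_adjacency(heads: list[int], kept, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(A, A+I, degrees) built through networkx, padded to size n."""
    g = tree_graph(heads).subgraph(set(kept))
    A = np.zeros((n, n))
    for i, j in g.edges:
        A[i - 1, j - 1] = A[j - 1, i - 1] = 1.0
    At = A + np.eye(n)
    return A, At, At.sum(axis=1)


def oracle_gcn(H: np.ndarray, A_tilde: np.ndarray, weights, biases) -> np.ndarray:
    """Dense per-node loop implementation of the L-layer graph convolution."""
    n = H.shape[0]
    d = A_tilde.sum(axis=1)
    h = H.copy()
    for W, b in zip(weights, biases):
        out = np.zeros((n, W.shape[1]))
        for i in range(n):
            acc = np.zeros(W.shape[1])
            for j in range(n):
                if A_tilde[i, j]:
                    acc += A_tilde[i, j] * (W.T @ h[j])
            out[i] = np.maximum(acc / d[i] + b, 0.0)
        h = out
    return h


def oracle_micro_f(gold, predicted) -> tuple[float, float, float, int, int, int]:
    """Naive counting scorer: returns (P, R, F, TP, FP, FN) in percent."""
    gold = list(set(gold))
    predicted = list(set(predicted))
    tp = sum(1 for p in predicted if p in gold)
    fp = sum(1 for p in predicted if p not in gold)
    fn = sum(1 for g in gold if g not in predicted)
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f, tp, fp, fn


def random_tree(rng: np.random.Generator, n: int) -> list[int]:
    """Uniform-ish random rooted tree as a head array."""
    order = rng.permutation(n) + 1
    heads = [0] * n
    for idx in range(1, n):
        parent = order[rng.integers(idx)]
        heads[order[idx] - 1] = int(parent)
    return heads


def random_spans(rng: np.random.Generator, n: int) -> tuple[set[int], set[int]]:
    k1 = int(rng.integers(1, min(3, n) + 1))
    k2 = int(rng.integers(1, min(3, n) + 1))
    s1 = set(int(v) for v in rng.choice(n, size=k1, replace=False) + 1)
    s2 = set(int(v) for v in rng.choice(n, size=k2, replace=False) + 1)
    return s1, s2
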