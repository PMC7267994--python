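"""Dependency-tree algorithms: LCA, path-centric pruning, adjacency matrices.

Tokens are 1-indexed; ``heads[i-1]`` is the head of token ``i`` and ``0``
marks the root.  Trees are treated as undirected, unlabeled graphs
throughout.  Pruning keeps the tokens of the LCA subtree whose tree-distance
to the dependency path between the two entity spans is at most ``N``;
``N = math.inf`` keeps the whole LCA subtree.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Collection, FrozenSet, Iterable, Sequence

import numpy as np

Span = Collection[int]


@dataclass(frozen=True)
class DependencyTree:
    """A rooted dependency tree given as a head array.

    Invariants (checked on construction): exactly one root, every head in
    ``{0} ∪ 1..n``, no cycles.
    """

    heads: tuple[int, ...]

    def __init__(self, heads: Sequence[int]):
        object.__setattr__(self, "heads", tuple(int(h) for h in heads))
        self._validate()

    def _validate(self) -> None:
        n = self.n
        if n == 0:
            raise ValueError("empty tree")
        roots = [i for i in self.tokens if self.head(i) == 0]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        for i in self.tokens:
            h = self.head(i)
            if not (0 <= h <= n):
                raise ValueError(f"token {i} has out-of-range head {h}")
            if h == i:
                raise ValueError(f"token {i} is its own head")
        # Cycle check: walking up from any token must reach the root.
        for i in self.tokens:
            seen = set()
            j = i
            while j != 0:
                if j in seen:
                    raise ValueError(f"cycle in head array involving token {j}")
                seen.add(j)
                j = self.head(j)

    @property
    def n(self) -> int:
        return len(self.heads)

    @property
    def tokens(self) -> range:
        return range(1, self.n + 1)

    @property
    def root(self) -> int:
        return next(i for i in self.tokens if self.head(i) == 0)

    def head(self, i: int) -> int:
        return self.heads[i - 1]

    def ancestors(self, i: int) -> list[int]:
        """Chain from ``i`` up to the root, inclusive of ``i``."""
        chain = [i]
        while self.head(chain[-1]) != 0:
            chain.append(self.head(chain[-1]))
        return chain

    def depth(self, i: int) -> int:
        return len(self.ancestors(i)) - 1

    def neighbors(self, i: int) -> list[int]:
        out = []
        if self.head(i) != 0:
            out.append(self.head(i))
        out.extend(j for j in self.tokens if self.head(j) == i)
        return out

    def subtree(self, root: int) -> frozenset[int]:
        """All descendants of ``root``, inclusive."""
        children: dict[int, list[int]] = {i: [] for i in self.tokens}
        for j in self.tokens:
            h = self.head(j)
            if h != 0:
                children[h].append(j)
        out, stack = set(), [root]
        while stack:
            v = stack.pop()
            out.add(v)
            stack.extend(children[v])
        return frozenset(out)


def _check_span(tree: DependencyTree, span: Span, name: str) -> frozenset[int]:
    s = frozenset(int(i) for i in span)
    if not s:
        raise ValueError(f"{name} is empty")
    if not all(1 <= i <= tree.n for i in s):
        raise ValueError(f"{name} {sorted(s)} out of range 1..{tree.n}")
    return s


def lca(tree: DependencyTree, span1: Span, span2: Span) -> int:
    """Lowest common ancestor (inclusive) of every token in both spans."""
    s1 = _check_span(tree, span1, "span1")
    s2 = _check_span(tree, span2, "span2")
    common: set[int] | None = None
    for i in s1 | s2:
        chain = set(tree.ancestors(i))
        common = chain if common is None else common & chain
    assert common  # the root is always a common ancestor
    return max(common, key=tree.depth)


def dependency_path(tree: DependencyTree, span1: Span, span2: Span) -> frozenset[int]:
    """Tokens on the dependency path between the two spans.

    For multi-token spans this is the union of the chains from each span's
    highest (shallowest) token up to the joint LCA, plus all entity tokens —
    entity tokens must survive pruning for entity pooling to be defined.
    """
    s1 = _check_span(tree, span1, "span1")
    s2 = _check_span(tree, span2, "span2")
    ancestor = lca(tree, s1, s2)
    path: set[int] = {ancestor} | set(s1) | set(s2)
    for span in (s1, s2):
        # Lowest index breaks depth ties, keeping the path deterministic.
        top = min(sorted(span), key=tree.depth)
        for v in tree.ancestors(top):
            path.add(v)
            if v == ancestor:
                break
    return frozenset(path)


def prune(tree: DependencyTree, chem_span: Span, prot_span: Span, N: int | float) -> frozenset[int]:
    """Path-centric pruning: tokens of the LCA subtree within distance ``N``
    of the dependency path between the spans.  Entity tokens are always kept.

    ``N=0`` prunes down to the path itself; ``N=math.inf`` keeps the entire
    LCA subtree.  The result is monotone non-decreasing in ``N``.
    """
    if not (N == math.inf or (isinstance(N, (int, np.integer)) and N >= 0)):
        raise ValueError(f"N must be a non-negative integer or inf, got {N!r}")
    s1 = _check_span(tree, chem_span, "chem_span")
    s2 = _check_span(tree, prot_span, "prot_span")
    ancestor = lca(tree, s1, s2)
    subtree = tree.subtree(ancestor)
    if N == math.inf:
        return subtree
    path = dependency_path(tree, s1, s2)
    # BFS from the path within the undirected tree restricted to the subtree.
    dist = {v: 0 for v in path}
    queue = deque(path)
    while queue:
        v = queue.popleft()
        if dist[v] == N:
            continue
        for w in tree.neighbors(v):
            if w in subtree and w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return frozenset(dist)


@dataclass(frozen=True)
class PrunedGraph:
    """Symmetric 0/1 adjacency over kept tokens, with self-loops on all nodes.

    ``A`` holds the kept dependency edges; ``A_tilde = A + I``; ``d[i]`` is
    the row sum of ``A_tilde`` (so pruned-out tokens have ``d == 1``).
    Matrices are 0-indexed: row ``i`` is token ``i+1``.
    """

    kept: frozenset[int]
    A: np.ndarray = field(repr=False)
    A_tilde: np.ndarray = field(repr=False)
    d: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.A.shape[0]


def build_adjacency(tree: DependencyTree, kept: Iterable[int], n: int | None = None) -> PrunedGraph:
    """Build the self-looped, pruned adjacency for a tree.

    An edge ``(i, j)`` is present iff both endpoints are kept and one heads
    the other.  Tokens outside ``kept`` retain only their self-loop.
    """
    if n is None:
        n = tree.n
    if n < tree.n:
        raise ValueError(f"n={n} smaller than tree size {tree.n}")
    kept_set = frozenset(int(i) for i in kept)
    if not kept_set <= set(range(1, tree.n + 1)):
        raise ValueError("kept contains out-of-range tokens")
    A = np.zeros((n, n), dtype=np.float64)
    for j in tree.tokens:
        h = tree.head(j)
        if h != 0 and j in kept_set and h in kept_set:
            A[j - 1, h - 1] = 1.0
            A[h - 1, j - 1] = 1.0
    A_tilde = A + np.eye(n)
    d = A_tilde.sum(axis=1)
    return PrunedGraph(kept=kept_set, A=A, A_tilde=A_tilde, d=d)
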