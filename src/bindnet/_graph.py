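"""Small deterministic graph primitives shared by the network modules."""

from __future__ import annotations

import numpy as np


class DisjointSet:
    """Union-find with path compression; used by Kruskal and component search."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


def edge_components(edges: list[tuple[int, int]], n_nodes: int) -> list[list[tuple[int, int]]]:
    """Group undirected edges into connected components.

    Returns one edge list per component, each sorted by (i, j); components are
    ordered by descending edge count, ties by smallest node index.
    """
    if not edges:
        return []
    ds = DisjointSet(n_nodes)
    for i, j in edges:
        ds.union(i, j)
    buckets: dict[int, list[tuple[int, int]]] = {}
    for i, j in edges:
        buckets.setdefault(ds.find(i), []).append((min(i, j), max(i, j)))
    comps = [sorted(b) for b in buckets.values()]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def is_connected(mask: np.ndarray) -> bool:
    """Whether the boolean adjacency matrix forms a single connected component."""
    n = mask.shape[0]
    if n == 0:
        return True
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        v = stack.pop()
        for u in np.flatnonzero(mask[v]):
            if not seen[u]:
                seen[u] = True
                stack.append(int(u))
    return bool(seen.all())
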