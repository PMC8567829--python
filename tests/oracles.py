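"""Independent brute-force oracles used to validate the graph metrics.

Everything here is written for clarity at tiny n (exhaustive loops, no
shared code with the package) so it can serve as ground truth.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def bfs_distances(A: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths by plain breadth-first search."""
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    for src in range(n):
        D[src, src] = 0
        frontier = [src]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if A[u, v] and D[src, v] == np.inf:
                        D[src, v] = d
                        nxt.append(v)
            frontier = nxt
    return D


def global_efficiency_brute(A: np.ndarray) -> float:
    n = A.shape[0]
    D = bfs_distances(A)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]):
                total += 1.0 / D[i, j]
    return total / (n * (n - 1))


def characteristic_path_length_brute(A: np.ndarray) -> float:
    n = A.shape[0]
    D = bfs_distances(A)
    vals = [D[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(D[i, j])]
    return float(np.mean(vals))


def clustering_brute(A: np.ndarray) -> tuple[np.ndarray, float]:
    n = A.shape[0]
    C = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if A[i, j]]
        k = len(nb)
        if k < 2:
            continue
        edges = sum(1 for u, v in combinations(nb, 2) if A[u, v])
        C[i] = 2.0 * edges / (k * (k - 1))
    return C, float(C.mean())


def local_efficiency_brute(A: np.ndarray) -> float:
    n = A.shape[0]
    total = 0.0
    for i in range(n):
        nb = [j for j in range(n) if A[i, j]]
        if len(nb) < 2:
            continue
        sub = A[np.ix_(nb, nb)]
        total += global_efficiency_brute(sub)
    return total / n


def modularity_brute(A: np.ndarray, communities) -> float:
    """Direct double-loop evaluation of Newman's Q for a partition."""
    n = A.shape[0]
    l2 = float(A.sum())
    k = A.sum(axis=1)
    s = list(communities)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if s[i] == s[j]:
                q += A[i, j] - k[i] * k[j] / l2
    return q / l2


def all_partitions(items: list):
    """Every set partition of ``items`` (exponential; keep n <= 6)."""
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for smaller in all_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[head] + smaller[i]] + smaller[i + 1:]
        yield [[head]] + smaller


def best_modularity_brute(A: np.ndarray) -> float:
    """Exhaustive maximum of Q over all partitions (n <= 6)."""
    n = A.shape[0]
    best = -np.inf
    for part in all_partitions(list(range(n))):
        lab = np.empty(n, dtype=int)
        for ci, block in enumerate(part):
            for node in block:
                lab[node] = ci
        best = max(best, modularity_brute(A, lab))
    return best


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    A = rng.random((n, n)) < p
    A = np.triu(A, k=1)
    A = A | A.T
    return A.astype(bool)
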