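"""Independent brute-force oracles for small graphs.

Everything here is deliberately naive — exhaustive path enumeration,
triple loops over node triples, direct formula evaluation — and shares no
code with the package implementation. Intended for graphs of at most ~8
nodes.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_shortest_paths(W: np.ndarray, s: int, t: int):
    """All shortest s-t paths under edge length 1/weight, by exhaustive
    simple-path enumeration. Returns (distance, list of node-paths);
    distance is inf when disconnected."""
    n = W.shape[0]
    best = np.inf
    paths: list[tuple[int, ...]] = []
    others = [v for v in range(n) if v not in (s, t)]
    for r in range(len(others) + 1):
        for mid in itertools.permutations(others, r):
            path = (s, *mid, t)
            length = 0.0
            ok = True
            for a, b in zip(path[:-1], path[1:]):
                if W[a, b] <= 0:
                    ok = False
                    break
                length += 1.0 / W[a, b]
            if not ok:
                continue
            if length < best - 1e-12:
                best = length
                paths = [path]
            elif abs(length - best) <= 1e-12:
                paths.append(path)
    return best, paths


def distance_matrix(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    D = np.zeros((n, n))
    for s in range(n):
        for t in range(n):
            if s != t:
                D[s, t] = enumerate_shortest_paths(W, s, t)[0]
    return D


def betweenness_percent(W: np.ndarray) -> np.ndarray:
    """Percentage of shortest paths through each node, over all unordered
    source-target pairs, normalized by (n-1)(n-2)/2."""
    n = W.shape[0]
    score = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            dist, paths = enumerate_shortest_paths(W, s, t)
            if not np.isfinite(dist) or not paths:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                frac = sum(v in p for p in paths) / len(paths)
                score[v] += frac
    pairs = (n - 1) * (n - 2) / 2
    return 100.0 * score / pairs


def onnela_clustering(W: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering: geometric mean of triangle weights
    normalized by the network maximum."""
    n = W.shape[0]
    wmax = W.max()
    out = np.zeros(n)
    if wmax == 0:
        return out
    Wh = W / wmax
    for v in range(n):
        nbrs = [u for u in range(n) if W[v, u] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        total = 0.0
        for u, w in itertools.combinations(nbrs, 2):
            total += (Wh[v, u] * Wh[v, w] * Wh[u, w]) ** (1 / 3)
        out[v] = 2 * total / (k * (k - 1))
    return out


def global_efficiency(W: np.ndarray) -> float:
    n = W.shape[0]
    if n < 2:
        return 0.0
    D = distance_matrix(W)
    total = 0.0
    for s in range(n):
        for t in range(n):
            if s != t and np.isfinite(D[s, t]) and D[s, t] > 0:
                total += 1.0 / D[s, t]
    return total / (n * (n - 1))


def local_efficiency(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if W[v, u] > 0]
        if len(nbrs) < 2:
            continue
        out[v] = global_efficiency(W[np.ix_(nbrs, nbrs)])
    return out


def modularity_q(W: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    """Direct double-sum evaluation of the resolution-modified modularity."""
    two_m = W.sum()
    if two_m == 0:
        return 0.0
    k = W.sum(axis=1)
    q = 0.0
    n = W.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += W[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m


def edge_components(edges: list[tuple[int, int]]) -> list[set[tuple[int, int]]]:
    """Connected components of an edge set via DFS over incident nodes."""
    adjacency: dict[int, set[int]] = {}
    for a, b in edges:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    seen: set[int] = set()
    comps = []
    for start in adjacency:
        if start in seen:
            continue
        stack, nodes = [start], set()
        while stack:
            v = stack.pop()
            if v in nodes:
                continue
            nodes.add(v)
            stack.extend(adjacency[v] - nodes)
        seen |= nodes
        comps.append({(a, b) for a, b in edges if a in nodes})
    return comps


def pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    """Hand-rolled pooled-variance two-sample t statistic."""
    na, nb = len(a), len(b)
    va = sum((x - np.mean(a)) ** 2 for x in a) / (na - 1)
    vb = sum((x - np.mean(b)) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if sp2 == 0:
        return 0.0
    return float((np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def random_weighted_graph(
    rng: np.random.Generator, n: int, p: float = 0.5
) -> np.ndarray:
    """Random symmetric weighted graph with zero diagonal, weights in
    (0, 1]."""
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                W[i, j] = W[j, i] = rng.uniform(0.05, 1.0)
    return W
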