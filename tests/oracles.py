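"""Independent brute-force oracles used by the test suite.

Everything here is written against the plain definitions (explicit BFS,
path enumeration, literal sums) and deliberately shares no code with the
package implementation.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- graphs

def bfs_distances(adj: np.ndarray, s: int) -> np.ndarray:
    n = len(adj)
    dist = np.full(n, np.inf)
    dist[s] = 0
    frontier = [s]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in range(n):
                if adj[u, v] and dist[v] == np.inf:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def all_pairs_distances(adj: np.ndarray) -> np.ndarray:
    return np.array([bfs_distances(adj, s) for s in range(len(adj))])


def degree(adj):
    return adj.sum(axis=1).astype(float)


def clustering(adj):
    n = len(adj)
    out = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(adj[a, b] for a, b in itertools.combinations(nbrs, 2))
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def efficiency_of(adj):
    n = len(adj)
    if n < 2:
        return 0.0
    dist = all_pairs_distances(adj)
    total = 0.0
    for s in range(n):
        for t in range(n):
            if s != t and np.isfinite(dist[s, t]):
                total += 1.0 / dist[s, t]
    return total / (n * (n - 1))


def local_efficiency(adj):
    n = len(adj)
    out = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        out[v] = efficiency_of(sub)
    return out


def eigenvector_centrality(adj):
    """Power iteration on A + I per connected component, L2-normalised."""
    n = len(adj)
    out = np.zeros(n)
    seen = np.zeros(n, bool)
    for s in range(n):
        if seen[s]:
            continue
        comp = [i for i, d in enumerate(bfs_distances(adj, s)) if np.isfinite(d)]
        seen[comp] = True
        if len(comp) == 1:
            continue
        a = adj[np.ix_(comp, comp)].astype(float) + np.eye(len(comp))
        x = np.ones(len(comp)) / math.sqrt(len(comp))
        for _ in range(1_000_000):
            nx_ = a @ x
            nx_ /= np.linalg.norm(nx_)
            if np.abs(nx_ - x).max() < 1e-14:
                x = nx_
                break
            x = nx_
        for i, v in zip(comp, x):
            out[i] = v
    return out


def closeness(adj):
    """(k-1)/sum(d) within the component, scaled by (k-1)/(n-1)."""
    n = len(adj)
    dist = all_pairs_distances(adj)
    out = np.zeros(n)
    for v in range(n):
        reach = [u for u in range(n) if u != v and np.isfinite(dist[v, u])]
        if not reach:
            continue
        k = len(reach)
        out[v] = (k / dist[v, reach].sum()) * (k / (n - 1))
    return out


def _all_shortest_paths(adj, s, t, dist_s):
    """Enumerate every shortest s-t path (lists of vertices)."""
    if not np.isfinite(dist_s[t]):
        return []
    paths = []

    def back(v, acc):
        if v == s:
            paths.append([s] + acc)
            return
        for u in range(len(adj)):
            if adj[u, v] and dist_s[u] == dist_s[v] - 1:
                back(u, [v] + acc)

    back(t, [])
    return paths


def betweenness(adj):
    """Unnormalised shortest-path betweenness by literal path enumeration."""
    n = len(adj)
    out = np.zeros(n)
    for s in range(n):
        dist_s = bfs_distances(adj, s)
        for t in range(s + 1, n):
            paths = _all_shortest_paths(adj, s, t, dist_s)
            if not paths:
                continue
            for p in paths:
                for v in p[1:-1]:
                    out[v] += 1.0 / len(paths)
    return out


def harmonic(adj):
    n = len(adj)
    dist = all_pairs_distances(adj)
    out = np.zeros(n)
    for v in range(n):
        out[v] = sum(
            1.0 / dist[v, u] for u in range(n) if u != v and np.isfinite(dist[v, u])
        )
    return out


def eccentricity(adj):
    n = len(adj)
    dist = all_pairs_distances(adj)
    out = np.zeros(n)
    for v in range(n):
        finite = dist[v][np.isfinite(dist[v])]
        out[v] = finite.max() if finite.size else 0.0
    return out


def pagerank(adj, alpha=0.85):
    """Direct linear solve with uniform dangling-node redistribution."""
    n = len(adj)
    deg = adj.sum(axis=1)
    m = np.zeros((n, n))
    for u in range(n):
        if deg[u] == 0:
            m[:, u] = 1.0 / n
        else:
            m[:, u] = adj[u] / deg[u]
    p = np.linalg.solve(np.eye(n) - alpha * m, np.full(n, (1 - alpha) / n))
    return p / p.sum()


def graph_density(adj):
    n = len(adj)
    if n < 2:
        return 0.0
    e = adj.sum() / 2.0
    return 2.0 * e / (n * (n - 1))


def assortativity(adj):
    """Pearson correlation of end-degrees over directed edge list."""
    n = len(adj)
    deg = adj.sum(axis=1)
    xs, ys = [], []
    for u in range(n):
        for v in range(n):
            if adj[u, v]:
                xs.append(deg[u])
                ys.append(deg[v])
    if not xs:
        return 0.0
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy))


def random_adjacency(n, p, rng):
    adj = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[i, j] = adj[j, i] = 1
    return adj


# ------------------------------------------------------ point processes

def ripley_k_literal(points, radii, a, b, area_um2):
    """Literal O(n^2) translation-corrected K sum."""
    n = len(points)
    out = np.zeros(len(radii))
    for ri, r in enumerate(radii):
        s = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                dx = abs(points[i, 0] - points[j, 0])
                dy = abs(points[i, 1] - points[j, 1])
                if math.hypot(dx, dy) <= r:
                    s += area_um2 / ((a - dx) * (b - dy))
        out[ri] = area_um2 / n**2 * s
    return out


# -------------------------------------------------------------- entropy

def entropy_literal(counts, base=2.0):
    """Frequency-table Shannon entropy of a count multiset."""
    freq = {}
    for c in counts:
        freq[c] = freq.get(c, 0) + 1
    total = sum(freq.values())
    h = 0.0
    for occ in freq.values():
        p = occ / total
        h -= p * math.log(p, base)
    return h


# -------------------------------------------------------------- higuchi

def higuchi_literal(x, k_max):
    """Loop-literal Higuchi curve-length dimension."""
    x = list(map(float, x))
    n = len(x)
    logs = []
    for k in range(1, k_max + 1):
        lks = []
        for m in range(1, k + 1):
            idxs = list(range(m - 1, n, k))
            if len(idxs) < 2:
                continue
            length = 0.0
            for a, bidx in zip(idxs[:-1], idxs[1:]):
                length += abs(x[bidx] - x[a])
            norm = (n - 1) / (((n - m) // k) * k)
            lks.append(length * norm / k)
        logs.append((math.log(1.0 / k), math.log(sum(lks) / len(lks))))
    xs = np.array([p[0] for p in logs])
    ys = np.array([p[1] for p in logs])
    return float(np.polyfit(xs, ys, 1)[0])
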