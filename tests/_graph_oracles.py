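"""Brute-force graph-metric oracles: exhaustive enumeration over all simple
paths / node triples of an 8-node weighted graph.  Deliberately independent
of the package implementation (no networkx, no Dijkstra)."""

from itertools import permutations

import numpy as np

_PERMS_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _perm_array(n_inter: int, k: int) -> np.ndarray:
    key = (n_inter, k)
    if key not in _PERMS_CACHE:
        if k == 0:
            _PERMS_CACHE[key] = np.empty((1, 0), dtype=int)
        else:
            _PERMS_CACHE[key] = np.array(
                list(permutations(range(n_inter), k)), dtype=int)
    return _PERMS_CACHE[key]


def _length_matrix(adj: np.ndarray) -> np.ndarray:
    L = np.full_like(adj, np.inf, dtype=float)
    nz = adj > 0
    L[nz] = 1.0 / adj[nz]
    return L


def brute_shortest_paths(adj: np.ndarray, directed: bool, tol: float = 1e-9):
    """All-pairs shortest distances and raw betweenness by enumerating every
    simple path between every ordered node pair."""
    n = adj.shape[0]
    L = _length_matrix(adj)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t or (not directed and s > t):
                continue
            inter = np.array([v for v in range(n) if v not in (s, t)])
            best = np.inf
            frac_through = np.zeros(n)
            n_best = 0
            for k in range(0, n - 1):
                perms = _perm_array(len(inter), k)
                mids = inter[perms] if k else np.empty((1, 0), dtype=int)
                paths = np.hstack([
                    np.full((mids.shape[0], 1), s), mids,
                    np.full((mids.shape[0], 1), t)])
                lengths = L[paths[:, :-1], paths[:, 1:]].sum(axis=1)
                m = np.min(lengths) if lengths.size else np.inf
                if m < best - tol * max(1.0, abs(best if best < np.inf else 0)):
                    best = m
                    n_best = 0
                    frac_through[:] = 0.0
                if not np.isfinite(best):
                    continue
                sel = lengths <= best * (1 + tol)
                if sel.any() and k > 0:
                    onehot = np.zeros((mids.shape[0], n))
                    onehot[np.arange(mids.shape[0])[:, None], mids] = 1.0
                    frac_through += onehot[sel].sum(axis=0)
                n_best += int(sel.sum())
            D[s, t] = best
            if not directed:
                D[t, s] = best
            if n_best > 0:
                bc += frac_through / n_best
    return D, bc


def brute_global_efficiency(adj: np.ndarray, directed: bool) -> float:
    D, _ = brute_shortest_paths(adj, directed)
    n = adj.shape[0]
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]) and D[i, j] > 0:
                acc += 1.0 / D[i, j]
    return acc / (n * (n - 1))


def brute_betweenness(adj: np.ndarray, directed: bool) -> np.ndarray:
    _, bc = brute_shortest_paths(adj, directed)
    return bc


def brute_clustering(adj: np.ndarray, directed: bool) -> np.ndarray:
    """Geometric-mean triangle clustering (Onnela; Fagiolo for directed),
    weights rescaled by the maximum, via explicit loops over node triples."""
    n = adj.shape[0]
    wmax = adj.max()
    w = adj / wmax if wmax > 0 else adj.copy()
    cw = np.cbrt(w)
    cc = np.zeros(n)
    if not directed:
        for i in range(n):
            nbrs = [j for j in range(n) if w[i, j] > 0]
            k = len(nbrs)
            if k < 2:
                continue
            tri = 0.0
            for a in range(k):
                for b in range(a + 1, k):
                    j, h = nbrs[a], nbrs[b]
                    tri += cw[i, j] * cw[i, h] * cw[j, h]
            cc[i] = 2.0 * tri / (k * (k - 1))
        return cc
    for i in range(n):
        d_tot = sum(int(w[i, j] > 0) + int(w[j, i] > 0)
                    for j in range(n) if j != i)
        d_bi = sum(int(w[i, j] > 0 and w[j, i] > 0)
                   for j in range(n) if j != i)
        denom = d_tot * (d_tot - 1) - 2 * d_bi
        if denom <= 0:
            continue
        tri = 0.0
        for j in range(n):
            for h in range(n):
                if len({i, j, h}) < 3:
                    continue
                tri += ((cw[i, j] + cw[j, i]) * (cw[i, h] + cw[h, i])
                        * (cw[j, h] + cw[h, j]))
        cc[i] = tri / (2.0 * denom)
    return cc
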