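"""Brute-force oracles used by the graph-metric tests.

Everything here is written from the definitions, independent of the
implementations in gradvar.topology: Floyd-Warshall all-pairs distances,
per-source shortest-path counting for betweenness, explicit triangle
enumeration for clustering, and direct formula sums.
"""

import numpy as np


def floyd_warshall(weights):
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def strength_oracle(weights):
    return np.array([weights[i].sum() for i in range(weights.shape[0])])


def global_efficiency_oracle(weights):
    n = weights.shape[0]
    d = floyd_warshall(weights)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if j != i and np.isfinite(d[i, j]) and d[i, j] > 0:
                acc += 1.0 / d[i, j]
        out[i] = acc / (n - 1) if n > 1 else 0.0
    return out


def local_efficiency_oracle(weights):
    n = weights.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = weights[np.ix_(nbrs, nbrs)]
        out[i] = global_efficiency_oracle(sub).mean()
    return out


def clustering_oracle(weights):
    n = weights.shape[0]
    wmax = weights.max()
    out = np.zeros(n)
    if wmax == 0:
        return out
    for i in range(n):
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        acc = 0.0
        for j in nbrs:
            for h in nbrs:
                if h != j and weights[j, h] > 0:
                    acc += (
                        (weights[i, j] / wmax)
                        * (weights[i, h] / wmax)
                        * (weights[j, h] / wmax)
                    ) ** (1.0 / 3.0)
        out[i] = acc / (k * (k - 1))
    return out


def betweenness_oracle(weights, tol=1e-12):
    """Shortest-path counting from the distance matrix: sigma[s][v] summed
    over predecessors on shortest paths, then pair-wise accumulation of
    sigma(s,v)*sigma(v,t)/sigma(s,t) for interior v."""
    n = weights.shape[0]
    d = floyd_warshall(weights)
    lengths = np.where(weights > 0, 1.0 / np.where(weights > 0, weights, 1.0), np.inf)

    sigma = np.zeros((n, n))
    for s in range(n):
        order = np.argsort(d[s], kind="stable")
        sigma[s, s] = 1.0
        for v in order:
            if v == s or not np.isfinite(d[s, v]):
                continue
            total = 0.0
            for u in range(n):
                if weights[u, v] > 0 and abs(d[s, u] + lengths[u, v] - d[s, v]) < tol:
                    total += sigma[s, u]
            sigma[s, v] = total

    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t or not np.isfinite(d[s, t]):
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if abs(d[s, v] + d[v, t] - d[s, t]) < tol and sigma[s, t] > 0:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc / 2.0  # undirected: each pair counted twice


def participation_oracle(weights, communities):
    n = weights.shape[0]
    comms = sorted(set(communities))
    out = np.zeros(n)
    for i in range(n):
        k_i = weights[i].sum()
        if k_i == 0:
            continue
        acc = 0.0
        for m in comms:
            k_im = sum(weights[i, j] for j in range(n) if communities[j] == m)
            acc += (k_im / k_i) ** 2
        out[i] = 1.0 - acc
    return out


def random_graph(rng, n, density=0.3):
    """Random symmetric weighted graph with weights in (0, 1]."""
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.uniform(size=iu.size) < density
    w[iu[mask], ju[mask]] = rng.uniform(0.05, 1.0, mask.sum())
    return w + w.T
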