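"""Independent brute-force / closed-form oracles used by the test suite.

Everything here is deliberately written from first principles (loops,
``math.comb``, textbook formulas) and never calls the code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm, t as t_dist


def nipals_pls_predict(X, Y, n_comp: int) -> np.ndarray:
    """Plain iterative NIPALS PLS2 regression, training-set predictions."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    Xd, Yd = X - xm, Y - ym
    Ws, Ps, Cs = [], [], []
    for _ in range(n_comp):
        u = Yd[:, 0].copy()
        for _ in range(5000):
            w = Xd.T @ u
            w = w / np.linalg.norm(w)
            t = Xd @ w
            c = Yd.T @ t / (t @ t)
            u_new = Yd @ c / (c @ c)
            if np.linalg.norm(u_new - u) < 1e-14 * (np.linalg.norm(u) + 1.0):
                u = u_new
                break
            u = u_new
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        c = Yd.T @ t / (t @ t)
        Xd = Xd - np.outer(t, p)
        Yd = Yd - np.outer(t, c)
        Ws.append(w), Ps.append(p), Cs.append(c)
    W, P, C = np.column_stack(Ws), np.column_stack(Ps), np.column_stack(Cs)
    B = W @ np.linalg.inv(P.T @ W) @ C.T
    return (X - xm) @ B + ym


def hypergeom_tail(k: int, M: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M population, K successes, N draws)."""
    total = math.comb(M, N)
    acc = 0
    for i in range(max(k, max(0, N - (M - K))), min(K, N) + 1):
        acc += math.comb(K, i) * math.comb(M - K, N - i)
    return acc / total


def bh_stepup(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = min(1.0, p[idx] * m / rank_from_top)
        running_min = min(running_min, val)
        adj[idx] = running_min
    return adj


def t_test_equal_var(a, b) -> tuple[float, float]:
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * t_dist.sf(abs(t), na + nb - 2)
    return t, p


def pearson_with_p(x, y) -> tuple[float, float]:
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    r = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = abs(r) * math.sqrt((n - 2) / (1 - r * r))
    return r, 2.0 * t_dist.sf(t, n - 2)


def mann_whitney_u(a, b) -> float:
    """U of the first sample by direct pair counting (ties count 1/2)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


def mann_whitney_exact_p(a, b) -> float:
    """Two-sided exact p by full enumeration of rank assignments (no ties)."""
    from itertools import combinations

    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    assert len(np.unique(pooled)) == len(pooled), "exact oracle needs tie-free data"
    na = len(a)
    u_obs = mann_whitney_u(a, b)
    mu = na * len(b) / 2.0
    count = 0
    total = 0
    idx = range(len(pooled))
    for comb in combinations(idx, na):
        grp_a = pooled[list(comb)]
        grp_b = np.delete(pooled, list(comb))
        u = mann_whitney_u(grp_a, grp_b)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def mann_whitney_normal_p(a, b) -> float:
    """Tie-corrected normal approximation with continuity correction,
    mirroring the conventional large-sample formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    n = na + nb
    u1 = mann_whitney_u(a, b)
    u = max(u1, na * nb - u1)
    mu = na * nb / 2.0
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3) - counts).sum())
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = (u - mu - 0.5) / math.sqrt(var)
    return min(1.0, 2.0 * norm.sf(z))


def betweenness_by_path_enumeration(nodes, edges) -> dict:
    """Betweenness centrality via explicit BFS shortest-path enumeration."""
    from collections import defaultdict, deque

    adj = defaultdict(set)
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    nodes = list(nodes)
    bc = {v: 0.0 for v in nodes}
    for s_i, s in enumerate(nodes):
        for t in nodes[s_i + 1 :]:
            # enumerate all shortest s-t paths
            dist = {s: 0}
            dq = deque([s])
            while dq:
                v = dq.popleft()
                for w in adj[v]:
                    if w not in dist:
                        dist[w] = dist[v] + 1
                        dq.append(w)
            if t not in dist:
                continue
            paths = []
            stack = [[s]]
            while stack:
                path = stack.pop()
                v = path[-1]
                if v == t:
                    paths.append(path)
                    continue
                for w in adj[v]:
                    if dist.get(w) == dist[v] + 1 and dist[w] <= dist[t]:
                        stack.append(path + [w])
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc
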