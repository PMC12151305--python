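"""Independent brute-force reference implementations for graph measures.

Deliberately naive algorithms (Floyd-Warshall, exhaustive simple-path
enumeration, direct triangle loops, full set-partition enumeration) used
only as oracles; they share no code with the package implementations.
"""

from __future__ import annotations

import itertools

import numpy as np


def fw_distances(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths on 1/weight lengths via Floyd-Warshall."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    ii, jj = np.nonzero(W)
    D[ii, jj] = 1.0 / W[ii, jj]
    for k in range(n):
        D = np.minimum(D, D[:, k][:, None] + D[k, :][None, :])
    return D


def components(W: np.ndarray) -> list[set[int]]:
    n = W.shape[0]
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        comp, stack = {s}, [s]
        while stack:
            u = stack.pop()
            for v in np.nonzero(W[u])[0]:
                if v not in comp:
                    comp.add(int(v))
                    stack.append(int(v))
        seen |= comp
        comps.append(comp)
    return comps


def distance_summary(W: np.ndarray) -> dict:
    n = W.shape[0]
    D = fw_distances(W)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    charpath = D[finite].mean()
    inv = np.zeros_like(D)
    inv[finite] = 1.0 / D[finite]
    geff = inv[off].mean()
    comp = max(components(W), key=len)
    idx = sorted(comp)
    if len(idx) > 1:
        Dc = D[np.ix_(idx, idx)]
        ecc = Dc.max(axis=1)
        radius, diameter = ecc.min(), ecc.max()
    else:
        radius = diameter = 0.0
    return {
        "characteristic_path_length": charpath,
        "global_efficiency": geff,
        "radius": radius,
        "diameter": diameter,
    }


def betweenness_by_enumeration(W: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Betweenness via exhaustive simple-path enumeration per node pair."""
    n = W.shape[0]
    adj = [list(np.nonzero(W[u])[0]) for u in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths: list[tuple[list[int], float]] = []

            def dfs(u: int, visited: list[int], length: float) -> None:
                if u == t:
                    paths.append((visited[:], length))
                    return
                for v in adj[u]:
                    if v not in visited:
                        visited.append(v)
                        dfs(v, visited, length + 1.0 / W[u, v])
                        visited.pop()

            dfs(s, [s], 0.0)
            if not paths:
                continue
            dmin = min(length for _, length in paths)
            shortest = [p for p, length in paths if length <= dmin + tol]
            for p in shortest:
                for node in p[1:-1]:
                    bc[node] += 1.0 / len(shortest)
    return bc


def degree_strength(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = W.shape[0]
    deg = np.zeros(n)
    stren = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                deg[i] += 1
                stren[i] += W[i, j]
    return deg, stren


def clustering_by_triangles(W: np.ndarray) -> tuple[np.ndarray, float]:
    """Geometric-mean weighted clustering and transitivity by triple loops."""
    n = W.shape[0]
    cyc = np.zeros(n)
    for i, j, k in itertools.permutations(range(n), 3):
        if W[i, j] > 0 and W[j, k] > 0 and W[k, i] > 0:
            cyc[i] += (W[i, j] * W[j, k] * W[k, i]) ** (1 / 3) / 2.0
    deg, _ = degree_strength(W)
    # each node's cyc holds one geometric-mean term per unordered triangle;
    # the convention counts ordered triangles, hence the factor 2
    denom = deg * (deg - 1)
    C = np.where(denom > 0, 2.0 * cyc / np.where(denom > 0, denom, 1), 0.0)
    total = denom.sum()
    T = 2.0 * cyc.sum() / total if total > 0 else 0.0
    return C, T


def local_efficiency_direct(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = np.nonzero(W[i])[0]
        if len(nb) < 2:
            continue
        sub = W[np.ix_(nb, nb)]
        D = fw_distances(sub)
        m = len(nb)
        vals = []
        for a in range(m):
            for b in range(m):
                if a != b:
                    vals.append(1.0 / D[a, b] if np.isfinite(D[a, b]) else 0.0)
        out[i] = np.mean(vals)
    return out


def eigenvector_by_power_iteration(
    W: np.ndarray, n_iter: int = 20000
) -> np.ndarray:
    comp = sorted(max(components(W), key=len))
    sub = W[np.ix_(comp, comp)]
    v = np.ones(len(comp))
    shift = np.abs(sub).sum() + 1.0  # keep iteration matrix positive definite
    M = sub + shift * np.eye(len(comp))
    for _ in range(n_iter):
        nv = M @ v
        v = nv / np.linalg.norm(nv)
    out = np.zeros(W.shape[0])
    out[comp] = np.abs(v)
    return out


def assortativity_by_correlation(W: np.ndarray) -> float:
    s = W.sum(axis=0)
    xs, ys = [], []
    for i in range(W.shape[0]):
        for j in range(W.shape[0]):
            if i != j and W[i, j] > 0:
                xs.append(s[i])
                ys.append(s[j])
    if np.std(xs) == 0 or np.std(ys) == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def set_partitions(items: list[int]):
    """All partitions of a set (restricted-growth-string enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1 :]
        yield [[first]] + partition


def modularity_q(W: np.ndarray, partition: list[list[int]], gamma: float = 1.0) -> float:
    two_m = W.sum()
    if two_m == 0:
        return 0.0
    s = W.sum(axis=0)
    q = 0.0
    for block in partition:
        idx = np.array(block)
        q += W[np.ix_(idx, idx)].sum() / two_m - gamma * (s[idx].sum() / two_m) ** 2
    return q


def max_modularity_by_enumeration(W: np.ndarray, gamma: float = 1.0) -> float:
    n = W.shape[0]
    return max(
        modularity_q(W, p, gamma) for p in set_partitions(list(range(n)))
    )
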