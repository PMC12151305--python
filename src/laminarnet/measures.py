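"""Weighted graph-theory measures and threshold-free (AUC) profiles.

All measures use the weighted conventions standard in functional
connectomics: shortest-path lengths on 1/weight, geometric-mean triangle
weights for clustering, Louvain modularity maximization, and strengths as
weighted degrees.  Matrices are assumed symmetric, nonnegative (after
normalization) with zero diagonal; weights in [0, 1].

Disconnection conventions (proportional thresholding disconnects sparse
graphs): characteristic path length averages finite distances only; global
efficiency counts disconnected pairs as zero; radius, diameter and
eigenvector centrality are computed on the largest connected component.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .containers import ConnectivityMatrix, DensityGrid, MeasureCurve
from .networks import threshold_proportional


def _as_weights(W) -> np.ndarray:
    if isinstance(W, ConnectivityMatrix):
        return W.weights
    return np.asarray(W, dtype=float)


def _length_graph(W: np.ndarray) -> csr_matrix:
    L = np.zeros_like(W)
    nz = W > 0
    L[nz] = 1.0 / W[nz]
    return csr_matrix(L)


def _components(W: np.ndarray) -> tuple[int, np.ndarray]:
    return connected_components(csr_matrix(W != 0), directed=False)


def _nx_graph(W: np.ndarray) -> nx.Graph:
    G = nx.from_numpy_array(W)
    for _, _, attrs in G.edges(data=True):
        attrs["length"] = 1.0 / attrs["weight"]
    return G


# ---------------------------------------------------------------------------
# composition


def composition_measures(W) -> dict:
    """Graph density, nodal degree and strength, largest cluster size."""
    W = _as_weights(W)
    n = W.shape[0]
    adj = W > 0
    degree = adj.sum(axis=0).astype(float)
    strength = W.sum(axis=0)
    n_edges = int(np.count_nonzero(np.triu(adj, 1)))
    density = n_edges / (n * (n - 1) / 2)
    _, labels = _components(W)
    largest = int(np.bincount(labels).max())
    return {
        "density": density,
        "degree": degree,
        "strength": strength,
        "largest_cluster_size": largest,
    }


# ---------------------------------------------------------------------------
# integration


def distance_measures(W) -> dict:
    """Characteristic path length, global efficiency, radius, diameter.

    Distances are shortest paths on 1/weight edge lengths.
    """
    W = _as_weights(W)
    n = W.shape[0]
    if not np.any(W > 0):
        raise ValueError("edgeless graph: distance measures undefined")
    D = shortest_path(_length_graph(W), method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    charpath = float(D[finite].mean())
    inv = np.zeros_like(D)
    inv[finite] = 1.0 / D[finite]
    global_eff = float(inv[off].mean())
    _, labels = _components(W)
    comp = labels == np.argmax(np.bincount(labels))
    Dc = D[np.ix_(comp, comp)]
    if Dc.shape[0] > 1:
        ecc = Dc.max(axis=1)
        radius, diameter = float(ecc.min()), float(ecc.max())
    else:
        radius = diameter = 0.0
    return {
        "characteristic_path_length": charpath,
        "global_efficiency": global_eff,
        "radius": radius,
        "diameter": diameter,
    }


# ---------------------------------------------------------------------------
# centrality


def betweenness_centrality(W) -> np.ndarray:
    """Fraction-of-shortest-paths betweenness on 1/weight lengths.

    Unnormalized counts with endpoints excluded; each unordered pair counted
    once.
    """
    W = _as_weights(W)
    G = _nx_graph(W)
    bc = nx.betweenness_centrality(G, weight="length", normalized=False)
    return np.array([bc[i] for i in range(W.shape[0])])


def eigenvector_centrality(W) -> np.ndarray:
    """Principal eigenvector of W, unit norm, nonnegative orientation.

    On disconnected graphs the centrality is computed on the largest
    component, zero elsewhere.
    """
    W = _as_weights(W)
    n = W.shape[0]
    _, labels = _components(W)
    comp = labels == np.argmax(np.bincount(labels))
    sub = W[np.ix_(comp, comp)]
    vals, vecs = np.linalg.eigh(sub)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    norm = np.linalg.norm(v)
    if norm > 0:
        v = v / norm
    out = np.zeros(n)
    out[comp] = v
    return out


# ---------------------------------------------------------------------------
# segregation


def clustering_measures(W) -> dict:
    """Weighted clustering, transitivity, local efficiency.

    Clustering uses the geometric-mean-of-triangle-weights convention:
    C_i = (W^(1/3))^3_ii / (k_i (k_i - 1)), with binary degree k.  Local
    efficiency is the global efficiency of each node's neighborhood
    subgraph.
    """
    W = _as_weights(W)
    n = W.shape[0]
    W3 = np.cbrt(W)
    cyc3 = np.diagonal(W3 @ W3 @ W3).copy()
    k = (W > 0).sum(axis=0).astype(float)
    denom = k * (k - 1)
    clustering = np.divide(
        cyc3, denom, out=np.zeros(n), where=denom > 0
    )
    total = denom.sum()
    transitivity = float(cyc3.sum() / total) if total > 0 else 0.0
    local_eff = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(W[i] > 0)
        if nb.size < 2:
            continue
        sub = W[np.ix_(nb, nb)]
        if not np.any(sub > 0):
            continue
        D = shortest_path(_length_graph(sub), method="D", directed=False)
        off = ~np.eye(nb.size, dtype=bool)
        inv = np.zeros_like(D)
        fin = np.isfinite(D) & off
        inv[fin] = 1.0 / D[fin]
        local_eff[i] = inv[off].mean()
    return {
        "clustering": clustering,
        "transitivity": transitivity,
        "local_efficiency": local_eff,
    }


def community_measures(
    W, gamma: float = 1.0, n_restarts: int = 10, seed: int | None = None
) -> dict:
    """Louvain modularity maximization and participation coefficients.

    Returns the best partition over ``n_restarts`` seeded restarts at
    resolution ``gamma``, its modularity Q, and the participation
    coefficient P_i = 1 - sum_m (k_im / k_i)^2 against that partition.
    """
    W = _as_weights(W)
    if not np.any(W > 0):
        raise ValueError("edgeless graph: modularity undefined")
    G = nx.from_numpy_array(W)
    rng = np.random.default_rng(seed)
    best_q, best_parts = -np.inf, None
    for _ in range(max(1, n_restarts)):
        parts = nx.community.louvain_communities(
            G, weight="weight", resolution=gamma, seed=int(rng.integers(2**31))
        )
        q = nx.community.modularity(G, parts, weight="weight", resolution=gamma)
        if q > best_q:
            best_q, best_parts = q, parts
    n = W.shape[0]
    membership = np.empty(n, dtype=int)
    for m, nodes in enumerate(best_parts):
        membership[list(nodes)] = m
    strength = W.sum(axis=0)
    participation = np.zeros(n)
    for i in range(n):
        if strength[i] <= 0:
            continue
        k_im = np.bincount(
            membership, weights=W[i], minlength=len(best_parts)
        )
        participation[i] = 1.0 - np.sum((k_im / strength[i]) ** 2)
    return {
        "partition": membership,
        "modularity": float(best_q),
        "participation": participation,
    }


def assortativity(W) -> float:
    """Weighted-degree assortativity (Newman's symmetric formula).

    Returns NaN when endpoint strengths have zero variance (e.g. regular
    graphs).
    """
    W = _as_weights(W)
    iu, ju = np.nonzero(np.triu(W, 1))
    if iu.size < 2:
        raise ValueError("need at least 2 edges for assortativity")
    s = W.sum(axis=0)
    ki, kj = s[iu], s[ju]
    m = float(iu.size)
    term = (np.sum(0.5 * (ki + kj)) / m) ** 2
    num = np.sum(ki * kj) / m - term
    den = np.sum(0.5 * (ki**2 + kj**2)) / m - term
    if np.isclose(den, 0.0):
        return float("nan")
    return float(num / den)


def small_worldness(
    W, n_null: int = 100, seed: int | None = None, swaps_per_edge: int = 10
) -> float:
    """Small-world sigma against degree-preserving rewired nulls.

    sigma = (C / C_null) / (L / L_null) with C the mean weighted clustering
    and L the characteristic path length; null statistics are averaged over
    ``n_null`` rewired matrices (weights follow edges through the swaps).
    """
    W = _as_weights(W)
    n = W.shape[0]
    n_comp, labels = _components(W)
    comp_sizes = np.bincount(labels)
    if comp_sizes.max() < 4:
        raise ValueError("largest component must have >= 4 nodes")
    C = float(clustering_measures(W)["clustering"].mean())
    L = distance_measures(W)["characteristic_path_length"]
    rng = np.random.default_rng(seed)
    iu, ju = np.nonzero(np.triu(W, 1))
    weights = W[iu, ju]
    E = iu.size
    c_null = np.empty(n_null)
    l_null = np.empty(n_null)
    for t in range(n_null):
        a = np.stack([iu.copy(), ju.copy()], axis=1)
        wts = weights.copy()
        present = set(map(tuple, np.sort(a, axis=1)))
        for _ in range(swaps_per_edge * E):
            e1, e2 = rng.integers(E, size=2)
            if e1 == e2:
                continue
            x, y = a[e1]
            u, v = a[e2]
            if rng.random() < 0.5:
                u, v = v, u
            # propose (x, v) and (u, y)
            if len({x, y, u, v}) < 4:
                continue
            new1 = tuple(sorted((x, v)))
            new2 = tuple(sorted((u, y)))
            if new1 in present or new2 in present:
                continue
            present.discard(tuple(sorted((x, y))))
            present.discard(tuple(sorted((u, v))))
            present.add(new1)
            present.add(new2)
            a[e1] = new1
            a[e2] = new2
        Wn = np.zeros_like(W)
        Wn[a[:, 0], a[:, 1]] = wts
        Wn = Wn + Wn.T
        c_null[t] = clustering_measures(Wn)["clustering"].mean()
        l_null[t] = distance_measures(Wn)["characteristic_path_length"]
    c_bar, l_bar = c_null.mean(), l_null.mean()
    if c_bar <= 0 or l_bar <= 0:
        raise ValueError("degenerate null statistics in small-worldness")
    return float((C / c_bar) / (L / l_bar))


# ---------------------------------------------------------------------------
# threshold-free summaries


def auc_over_grid(values, grid: DensityGrid | Sequence[float]) -> float | np.ndarray:
    """Trapezoidal AUC of a measure over the density grid.

    ``values`` may be (G,) for a global measure or (G, N) for a nodal one.
    """
    x = grid.as_array() if isinstance(grid, DensityGrid) else np.asarray(grid, float)
    v = np.asarray(values, dtype=float)
    if v.shape[0] != len(x):
        raise ValueError("values and grid must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 grid points")
    out = np.trapezoid(v, x=x, axis=0)
    return float(out) if out.ndim == 0 else out


def layer_aggregate(
    nodal_values: np.ndarray, node_labels: Sequence[tuple[int, int]]
) -> dict[int, float]:
    """Mean of a nodal measure per depth, over that depth's R nodes."""
    v = np.asarray(nodal_values, dtype=float)
    if v.shape[0] != len(node_labels):
        raise ValueError("nodal values misaligned with node labels")
    depths = sorted({d for _, d in node_labels})
    out = {}
    for depth in depths:
        idx = [i for i, (_, d) in enumerate(node_labels) if d == depth]
        out[depth] = float(v[idx].mean())
    return out


def layer_wise_density(cm: ConnectivityMatrix) -> dict[int, float]:
    """Realized density of each within-depth diagonal block."""
    out = {}
    for depth in cm.depths:
        idx = cm.layer_index(depth)
        block = cm.weights[np.ix_(idx, idx)]
        n = len(idx)
        out[depth] = np.count_nonzero(np.triu(block, 1)) / (n * (n - 1) / 2)
    return out


# ---------------------------------------------------------------------------
# measure registry and grid profiles

#: cheap closed-form measures used by default in Monte-Carlo simulations
FAST_GLOBAL = (
    "density",
    "largest_cluster_size",
    "characteristic_path_length",
    "global_efficiency",
    "radius",
    "diameter",
    "transitivity",
    "assortativity",
)
FAST_NODAL = (
    "degree",
    "strength",
    "clustering",
    "local_efficiency",
    "eigenvector",
    "betweenness",
)

FULL_GLOBAL = FAST_GLOBAL + ("modularity",)
FULL_NODAL = FAST_NODAL + ("participation",)


def graph_summary(
    W,
    global_measures: Iterable[str] = FAST_GLOBAL,
    nodal_measures: Iterable[str] = FAST_NODAL,
    seed: int | None = None,
) -> dict:
    """Evaluate a set of named measures on one thresholded matrix.

    Returns {name: scalar} for global measures and {name: (N,) array} for
    nodal ones.  Unknown names raise.
    """
    W = _as_weights(W)
    global_measures = tuple(global_measures)
    nodal_measures = tuple(nodal_measures)
    wanted = set(global_measures) | set(nodal_measures)
    out: dict = {}
    comp_keys = {"density", "degree", "strength", "largest_cluster_size"}
    if wanted & comp_keys:
        out.update(composition_measures(W))
    dist_keys = {
        "characteristic_path_length",
        "global_efficiency",
        "radius",
        "diameter",
    }
    if wanted & dist_keys:
        if np.any(W > 0):
            out.update(distance_measures(W))
        else:
            out.update({k: 0.0 for k in dist_keys})
    clus_keys = {"clustering", "transitivity", "local_efficiency"}
    if wanted & clus_keys:
        out.update(clustering_measures(W))
    if "eigenvector" in wanted:
        out["eigenvector"] = eigenvector_centrality(W)
    if "betweenness" in wanted:
        out["betweenness"] = betweenness_centrality(W)
    if "assortativity" in wanted:
        n_edges = np.count_nonzero(np.triu(W, 1))
        out["assortativity"] = assortativity(W) if n_edges >= 2 else float("nan")
    if {"modularity", "participation"} & wanted:
        if np.any(W > 0):
            cm = community_measures(W, seed=seed)
            out["modularity"] = cm["modularity"]
            out["participation"] = cm["participation"]
        else:
            out["modularity"] = 0.0
            out["participation"] = np.zeros(W.shape[0])
    unknown = wanted - set(out)
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")
    return {k: v for k, v in out.items() if k in wanted}


def measure_profile(
    cm: ConnectivityMatrix,
    grid: DensityGrid = DensityGrid(),
    global_measures: Iterable[str] = FAST_GLOBAL,
    nodal_measures: Iterable[str] = FAST_NODAL,
    seed: int | None = None,
) -> dict[str, MeasureCurve]:
    """Threshold a normalized matrix along the density grid and evaluate
    every requested measure, returning per-measure curves with AUCs.
    """
    global_measures = tuple(global_measures)
    nodal_measures = tuple(nodal_measures)
    n = cm.n_nodes
    g = len(grid)
    values: dict[str, np.ndarray] = {
        m: np.zeros(g) for m in global_measures
    }
    values.update({m: np.zeros((g, n)) for m in nodal_measures})
    for gi, density in enumerate(grid.values):
        thr = threshold_proportional(cm, density)
        summary = graph_summary(
            thr.weights, global_measures, nodal_measures, seed=seed
        )
        for m in global_measures:
            values[m][gi] = summary[m]
        for m in nodal_measures:
            values[m][gi] = summary[m]
    curves = {}
    for m in global_measures:
        curves[m] = MeasureCurve(
            measure_name=m,
            scope="global",
            values=values[m],
            grid=grid,
            auc=auc_over_grid(np.nan_to_num(values[m]), grid),
        )
    for m in nodal_measures:
        curves[m] = MeasureCurve(
            measure_name=m,
            scope="nodal",
            values=values[m],
            grid=grid,
            auc=auc_over_grid(values[m], grid),
        )
    return curves
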