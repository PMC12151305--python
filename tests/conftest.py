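from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from laminarnet.containers import ConnectivityMatrix, LaminarTimeSeries, channel_labels


def random_weights(n: int, rng: np.random.Generator, p: float = 0.6) -> np.ndarray:
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    upper = np.triu((rng.random((n, n)) < p) * rng.uniform(0.2, 1.0, (n, n)), 1)
    return upper + upper.T


def weighted_atlas_graphs(
    max_nodes: int = 7, seed: int = 0
) -> list[np.ndarray]:
    """Every connected graph with 3..max_nodes nodes, randomly weighted."""
    rng = np.random.default_rng(seed)
    out = []
    for G in nx.graph_atlas_g()[1:]:
        n = G.number_of_nodes()
        if n < 3 or n > max_nodes or not nx.is_connected(G):
            continue
        W = np.zeros((n, n))
        for u, v in G.edges():
            W[u, v] = W[v, u] = rng.uniform(0.2, 1.0)
        out.append(W)
    return out


@pytest.fixture(scope="session")
def atlas_graphs() -> list[np.ndarray]:
    return weighted_atlas_graphs()


def make_ts(
    data: np.ndarray, n_roi: int, n_depths: int, tr: float = 2.8, pid: str = "sub-01"
) -> LaminarTimeSeries:
    return LaminarTimeSeries(
        participant_id=pid,
        data=data,
        channel_labels=tuple(channel_labels(n_roi, n_depths)),
        tr_seconds=tr,
    )


def matrix(
    weights: np.ndarray, n_depths: int = 1, tag: str = "layer_by_layer"
) -> ConnectivityMatrix:
    n = weights.shape[0]
    r = n // n_depths
    return ConnectivityMatrix(
        weights=weights,
        node_labels=tuple(channel_labels(r, n_depths)),
        pipeline_tag=tag,
    )
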