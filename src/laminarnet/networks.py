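"""Functional network construction: correlation, normalization, thresholding.

Two parallel constructions are supported.  The layer-by-layer pipeline
correlates ROIs within one cortical depth, giving one R x R matrix per
depth.  The multilayer pipeline correlates every depth-resolved channel
with every other, giving a single (R*D) x (R*D) supra-adjacency matrix in
depth-major node order; within-layer blocks and the between-layer remainder
are extracted from the thresholded supra matrix.

Weights are Fisher z-transformed Pearson correlations.  "Normalization"
zeroes negative weights and rescales by the maximum weight, the standard
weight-conversion convention for weighted graph analysis; proportional
thresholding then retains the top fraction of positive weights.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .containers import ConnectivityMatrix, LaminarTimeSeries

FISHER_CLAMP = 1.0 - 1e-7


class ZeroVarianceChannelError(ValueError):
    """A channel with zero variance cannot be correlated."""

    def __init__(self, channels: list[tuple[int, int]]):
        self.channels = channels
        labels = ", ".join(f"roi{r}_depth{d}" for r, d in channels)
        super().__init__(f"zero-variance channel(s): {labels}")


def correlation_fisher(
    ts: LaminarTimeSeries, node_subset: Sequence[int] | None = None
) -> ConnectivityMatrix:
    """Pairwise Pearson correlation with Fisher z-transformation.

    ``node_subset`` selects channel columns (default: all).  |r| is clamped
    at 1 - 1e-7 so perfectly correlated channels keep a finite weight; the
    diagonal is zeroed.
    """
    idx = (
        np.arange(ts.data.shape[1])
        if node_subset is None
        else np.asarray(list(node_subset), dtype=int)
    )
    if idx.size == 0:
        raise ValueError("node_subset must be non-empty")
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points for correlation")
    X = ts.data[:, idx]
    sd = X.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ZeroVarianceChannelError([ts.channel_labels[idx[i]] for i in dead])
    r = np.corrcoef(X, rowvar=False)
    r = np.clip(r, -FISHER_CLAMP, FISHER_CLAMP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    labels = tuple(ts.channel_labels[i] for i in idx)
    tag = "multilayer" if len({d for _, d in labels}) > 1 else "layer_by_layer"
    return ConnectivityMatrix(weights=z, node_labels=labels, pipeline_tag=tag)


def build_layer_by_layer(ts: LaminarTimeSeries) -> list[ConnectivityMatrix]:
    """One R x R Fisher-z correlation matrix per cortical depth."""
    depths = sorted({d for _, d in ts.channel_labels})
    matrices = []
    for depth in depths:
        idx = [i for i, (_, d) in enumerate(ts.channel_labels) if d == depth]
        matrices.append(correlation_fisher(ts, idx))
    return matrices


def build_multilayer(ts: LaminarTimeSeries) -> ConnectivityMatrix:
    """(R*D) x (R*D) supra-adjacency matrix in depth-major node order."""
    expected = sorted(
        range(len(ts.channel_labels)),
        key=lambda i: (ts.channel_labels[i][1], ts.channel_labels[i][0]),
    )
    return correlation_fisher(ts, expected)


def normalize_weights(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """Zero negative weights and rescale so the maximum weight is 1."""
    w = np.where(cm.weights > 0, cm.weights, 0.0)
    wmax = w.max()
    if wmax <= 0:
        raise ValueError("matrix has no positive weight to normalize")
    return ConnectivityMatrix(
        weights=w / wmax,
        node_labels=cm.node_labels,
        pipeline_tag=cm.pipeline_tag,
        density=cm.density,
    )


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def threshold_proportional(
    cm: ConnectivityMatrix, density: float
) -> ConnectivityMatrix:
    """Retain the ``round(density * N(N-1)/2)`` largest positive weights.

    Ties are broken by ascending (i, j) index for reproducibility.  If fewer
    positive weights exist than requested, all are kept and the realized
    density is recorded.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n = cm.n_nodes
    n_pairs = n * (n - 1) // 2
    k = _round_half_away(density * n_pairs)
    iu, ju = np.triu_indices(n, 1)
    w = cm.weights[iu, ju]
    positive = np.flatnonzero(w > 0)
    # sort by descending weight, then ascending (i, j)
    order = positive[np.lexsort((ju[positive], iu[positive], -w[positive]))]
    keep = order[:k]
    out = np.zeros_like(cm.weights)
    out[iu[keep], ju[keep]] = w[keep]
    out = out + out.T
    return ConnectivityMatrix(
        weights=out,
        node_labels=cm.node_labels,
        pipeline_tag=cm.pipeline_tag,
        density=len(keep) / n_pairs,
    )


def extract_within_layer(cm: ConnectivityMatrix, depth: int) -> ConnectivityMatrix:
    """Diagonal block of one depth from a (thresholded) multilayer matrix."""
    if cm.pipeline_tag != "multilayer":
        raise ValueError("within-layer extraction requires a multilayer matrix")
    if depth not in cm.depths:
        raise ValueError(f"depth {depth} not present (have {cm.depths})")
    idx = cm.layer_index(depth)
    block = cm.weights[np.ix_(idx, idx)]
    out = ConnectivityMatrix(
        weights=block,
        node_labels=tuple(cm.node_labels[i] for i in idx),
        pipeline_tag="within_layer",
    )
    out.density = out.realized_density()
    return out


def extract_between_layer(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """Zero every within-depth diagonal block of a multilayer matrix."""
    if cm.pipeline_tag != "multilayer":
        raise ValueError("between-layer extraction requires a multilayer matrix")
    w = cm.weights.copy()
    for depth in cm.depths:
        idx = cm.layer_index(depth)
        w[np.ix_(idx, idx)] = 0.0
    out = ConnectivityMatrix(
        weights=w, node_labels=cm.node_labels, pipeline_tag="between_layer"
    )
    out.density = out.realized_density()
    return out
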