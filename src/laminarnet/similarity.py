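"""Edge consistency/variability across participants and matrix similarity.

Edge dispersion is computed on the raw (unthresholded, unnormalized)
Fisher-z multilayer weights: the per-edge standard deviation across
participants is ranked, the extreme 5% (lowest sd = consistency, highest sd
= variability) is selected, and the selected edges are tabulated per
layer-pair block of the supra-adjacency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import ConnectivityMatrix, DensityGrid, MeasureCurve
from .networks import extract_within_layer, threshold_proportional


@dataclass
class EdgeDispersionBlocks:
    """Block-wise percentages of the selected extreme-dispersion edges.

    ``block_pct[(di, dj)]`` (di <= dj) holds the percentage of selected
    edges joining layers di and dj; the percentages sum to 100.  Per-layer
    totals assign within-layer blocks fully to their layer and split
    between-layer blocks half to each participating layer.
    """

    mode: str  # "consistency" | "variability"
    block_pct: dict[tuple[int, int], float]
    per_layer_pct: dict[int, float]
    n_selected: int


def edge_dispersion(
    matrices: Sequence[ConnectivityMatrix],
    mode: str = "consistency",
    fraction: float = 0.05,
) -> EdgeDispersionBlocks:
    """Tabulate the lowest- (consistency) or highest-sd (variability) edges.

    ``matrices`` are unthresholded multilayer matrices with identical node
    labels, one per participant.  floor(fraction * E) edges are selected;
    ties are broken by ascending edge index.
    """
    if mode not in ("consistency", "variability"):
        raise ValueError("mode must be 'consistency' or 'variability'")
    if len(matrices) < 2:
        raise ValueError("need at least 2 participants")
    labels = matrices[0].node_labels
    for cm in matrices[1:]:
        if cm.node_labels != labels:
            raise ValueError("participants have mismatched node labels")
    n = matrices[0].n_nodes
    iu, ju = np.triu_indices(n, 1)
    stack = np.stack([cm.weights[iu, ju] for cm in matrices], axis=0)
    sd = stack.std(axis=0, ddof=1)
    n_select = int(np.floor(fraction * iu.size))
    order = np.argsort(sd, kind="stable")  # ascending sd, ties by index
    if mode == "variability":
        order = np.argsort(-sd, kind="stable")
    selected = order[:n_select]
    depths = sorted({d for _, d in labels})
    depth_of = np.array([d for _, d in labels])
    di = depth_of[iu[selected]]
    dj = depth_of[ju[selected]]
    lo = np.minimum(di, dj)
    hi = np.maximum(di, dj)
    block_pct: dict[tuple[int, int], float] = {}
    for a in depths:
        for b in depths:
            if a <= b:
                count = int(np.sum((lo == a) & (hi == b)))
                block_pct[(a, b)] = 100.0 * count / n_select if n_select else 0.0
    per_layer = {}
    for d in depths:
        total = block_pct[(d, d)]
        for other in depths:
            if other == d:
                continue
            key = (min(d, other), max(d, other))
            total += 0.5 * block_pct[key]
        per_layer[d] = total
    return EdgeDispersionBlocks(
        mode=mode, block_pct=block_pct, per_layer_pct=per_layer, n_selected=n_select
    )


def cosine_similarity(A: ConnectivityMatrix | np.ndarray, B) -> float:
    """Cosine of the upper-triangular weight vectors of two matrices.

    Returns NaN when either vector is all-zero.
    """
    a = A.weights if isinstance(A, ConnectivityMatrix) else np.asarray(A, float)
    b = B.weights if isinstance(B, ConnectivityMatrix) else np.asarray(B, float)
    if a.shape != b.shape:
        raise ValueError("matrices must share shape")
    iu, ju = np.triu_indices(a.shape[0], 1)
    x, y = a[iu, ju], b[iu, ju]
    nx_, ny_ = np.linalg.norm(x), np.linalg.norm(y)
    if nx_ == 0 or ny_ == 0:
        return float("nan")
    return float(np.dot(x, y) / (nx_ * ny_))


def method_similarity_curves(
    layer_matrices: Sequence[ConnectivityMatrix],
    multilayer: ConnectivityMatrix,
    grid: DensityGrid = DensityGrid(),
) -> dict[int, MeasureCurve]:
    """Cosine similarity of layer-by-layer vs within-layer construction.

    For each depth and each grid density, the independently thresholded
    layer-by-layer matrix is compared with the within-layer block extracted
    from the jointly thresholded multilayer matrix.  Inputs are normalized,
    unthresholded matrices.
    """
    depths = multilayer.depths
    if len(layer_matrices) != len(depths):
        raise ValueError(
            "need one layer-by-layer matrix per depth of the multilayer matrix"
        )
    values = {d: np.zeros(len(grid)) for d in depths}
    for gi, density in enumerate(grid.values):
        thr_ml = threshold_proportional(multilayer, density)
        for d, lbl in zip(depths, layer_matrices):
            within = extract_within_layer(thr_ml, d)
            thr_lbl = threshold_proportional(lbl, density)
            values[d][gi] = cosine_similarity(thr_lbl, within)
    return {
        d: MeasureCurve(
            measure_name="cosine_similarity",
            scope="global",
            values=values[d],
            grid=grid,
            auc=float(np.trapezoid(np.nan_to_num(values[d]), x=grid.as_array())),
        )
        for d in depths
    }
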