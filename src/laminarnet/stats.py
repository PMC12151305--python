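"""Layer-wise statistical comparison of threshold-free (AUC) measures.

Global measures (and layer-averaged nodal measures) are compared across
layers with a one-way ANOVA and Benjamini-Hochberg FDR control across
measures (alpha = 0.05).  Individual nodal measures are compared per ROI
across its depth copies with Holm step-down control across ROIs within each
measure (alpha = 0.01).  Each comparison carries the peak layer: the layer
whose group-mean AUC is highest (ties to the lowest layer index).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import AtlasMetadata

_MT_METHOD = {"benjamini_hochberg": "fdr_bh", "holm": "holm"}


@dataclass
class LayerComparisonResult:
    measure: str
    scope: str  # "global" | "nodal"
    node: int | None
    F: float
    p: float
    p_adjusted: float
    significant: bool
    peak_layer: int


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way F test across k groups.

    Degenerate inputs: zero within-group variance with equal means gives
    (F=0, p=1); with unequal means gives (inf, 0) with a warning.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    pooled = np.concatenate(arrays)
    grand = pooled.mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    # variance tolerances relative to the data's magnitude, so that values
    # identical up to floating-point arithmetic count as identical
    ref = max(float(np.sum(pooled**2)), np.finfo(float).tiny)
    tol = 1e-12 * ref
    if ssb + ssw <= tol:
        return 0.0, 1.0
    if ssw <= tol:
        warnings.warn("zero within-group variance with unequal means")
        return float("inf"), 0.0
    F = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return float(F), p


def adjust_pvalues(
    pvals: Sequence[float], method: str = "benjamini_hochberg", alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Multiple-comparison adjustment; returns (p_adjusted, rejected)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in _MT_METHOD:
        raise ValueError(f"method must be one of {sorted(_MT_METHOD)}")
    rejected, p_adj, _, _ = multipletests(p, alpha=alpha, method=_MT_METHOD[method])
    return p_adj, rejected


def _peak_layer(group_means: dict[int, float]) -> int:
    best = max(group_means.values())
    return min(layer for layer, m in group_means.items() if np.isclose(m, best))


def compare_layers(
    auc_table: pd.DataFrame,
    scope: str = "global",
    method: str | None = None,
    alpha: float | None = None,
) -> pd.DataFrame:
    """ANOVA of per-layer AUC distributions with multiplicity control.

    ``auc_table`` is long-format with columns participant, layer, measure,
    auc (+ node for nodal scope).  Global scope: one ANOVA per measure,
    groups = layers, BH across measures at alpha 0.05.  Nodal scope: one
    ANOVA per (measure, node) with the node's depth copies as groups, Holm
    across nodes within each measure at alpha 0.01.
    """
    if scope not in ("global", "nodal"):
        raise ValueError("scope must be 'global' or 'nodal'")
    method = method or ("benjamini_hochberg" if scope == "global" else "holm")
    alpha = alpha if alpha is not None else (0.05 if scope == "global" else 0.01)
    required = {"participant", "layer", "measure", "auc"}
    if scope == "nodal":
        required.add("node")
    missing = required - set(auc_table.columns)
    if missing:
        raise ValueError(f"auc_table missing columns: {sorted(missing)}")
    rows: list[dict] = []
    if scope == "global":
        for measure, sub in auc_table.groupby("measure", sort=True):
            groups, means = _layer_groups(sub)
            F, p = one_way_anova(groups)
            rows.append(
                {
                    "measure": measure,
                    "scope": scope,
                    "node": None,
                    "F": F,
                    "p": p,
                    "peak_layer": _peak_layer(means),
                }
            )
        df = pd.DataFrame(rows)
        p_adj, rej = adjust_pvalues(df["p"], method, alpha)
        df["p_adjusted"], df["significant"] = p_adj, rej
        return df
    for measure, msub in auc_table.groupby("measure", sort=True):
        mrows = []
        for node, sub in msub.groupby("node", sort=True):
            groups, means = _layer_groups(sub)
            F, p = one_way_anova(groups)
            mrows.append(
                {
                    "measure": measure,
                    "scope": scope,
                    "node": int(node),
                    "F": F,
                    "p": p,
                    "peak_layer": _peak_layer(means),
                }
            )
        mdf = pd.DataFrame(mrows)
        p_adj, rej = adjust_pvalues(mdf["p"], method, alpha)
        mdf["p_adjusted"], mdf["significant"] = p_adj, rej
        rows.extend(mdf.to_dict("records"))
    return pd.DataFrame(rows)


def _layer_groups(sub: pd.DataFrame) -> tuple[list[np.ndarray], dict[int, float]]:
    layers = sorted(sub["layer"].unique())
    sizes = {lay: (sub["layer"] == lay).sum() for lay in layers}
    if len(set(sizes.values())) > 1:
        raise ValueError(f"unbalanced layer cells: {sizes}")
    groups = [sub.loc[sub["layer"] == lay, "auc"].to_numpy() for lay in layers]
    means = {int(lay): float(g.mean()) for lay, g in zip(layers, groups)}
    return groups, means


def tabulate_regions(
    nodal_results: pd.DataFrame, atlas: AtlasMetadata
) -> pd.DataFrame:
    """Count significant ROIs per region x hemisphere for each measure."""
    known = set(atlas.table["roi_id"])
    unknown = set(nodal_results["node"].dropna().astype(int)) - known
    if unknown:
        raise ValueError(f"unknown ROI ids: {sorted(unknown)}")
    meta = atlas.table.set_index("roi_id")[["region", "hemisphere"]]
    df = nodal_results.copy()
    df["region"] = df["node"].map(meta["region"])
    df["hemisphere"] = df["node"].map(meta["hemisphere"])
    counts = (
        df[df["significant"]]
        .groupby(["measure", "region", "hemisphere"])
        .size()
        .rename("n_significant")
        .reset_index()
    )
    # complete the table with zeros and region denominators
    denom = (
        atlas.table.groupby(["region", "hemisphere"]).size().rename("n_roi")
    )
    full = []
    for measure in sorted(nodal_results["measure"].unique()):
        base = denom.reset_index()
        base["measure"] = measure
        full.append(base)
    table = pd.concat(full, ignore_index=True).merge(
        counts, on=["measure", "region", "hemisphere"], how="left"
    )
    table["n_significant"] = table["n_significant"].fillna(0).astype(int)
    return table[["measure", "region", "hemisphere", "n_significant", "n_roi"]]


def thickness_confound_test(
    nodal_results: pd.DataFrame,
    atlas: AtlasMetadata,
    min_nodes: int = 10,
) -> pd.DataFrame:
    """Two-sample t test of ROI thickness, significant vs nonsignificant.

    Run per measure, only when the significant set exceeds ``min_nodes``
    and both groups have >= 2 members; otherwise the row records the skip
    reason.
    """
    thickness = atlas.table.set_index("roi_id")["thickness_mm"]
    rows = []
    for measure, sub in nodal_results.groupby("measure", sort=True):
        sig_nodes = sub.loc[sub["significant"], "node"].astype(int)
        non_nodes = sub.loc[~sub["significant"], "node"].astype(int)
        row: dict = {
            "measure": measure,
            "n_significant": len(sig_nodes),
            "t": np.nan,
            "p": np.nan,
            "skipped": None,
        }
        if len(sig_nodes) <= min_nodes:
            row["skipped"] = f"<= {min_nodes} significant nodes"
        elif len(non_nodes) < 2:
            row["skipped"] = "fewer than 2 nonsignificant nodes"
        else:
            a = thickness.loc[sig_nodes].to_numpy()
            b = thickness.loc[non_nodes].to_numpy()
            if np.allclose(a.std(), 0) and np.allclose(b.std(), 0) and np.isclose(
                a.mean(), b.mean()
            ):
                row["t"], row["p"] = 0.0, 1.0
            else:
                t, p = sps.ttest_ind(a, b)
                row["t"], row["p"] = float(t), float(p)
        rows.append(row)
    return pd.DataFrame(rows)
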