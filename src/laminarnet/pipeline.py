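"""End-to-end orchestration: conditioning -> networks -> AUC tables -> stats.

The long-format AUC tables produced here are the interface between the
graph-measure stage and the group statistics:

``global`` table: participant, pipeline, layer, measure, auc — one row per
global measure (or layer-averaged nodal measure, named ``avg_<measure>``)
per layer.

``nodal`` table: participant, pipeline, layer, measure, node, auc — one row
per ROI per layer per nodal measure.

Pipelines follow the two parallel constructions: ``layer_by_layer``
(independent per-depth matrices, independently thresholded) and the
multilayer family (``multilayer``, ``within_layer``, ``between_layer``)
derived from the jointly thresholded supra-adjacency matrix.  Global graph
measures are only reported for layer_by_layer and within_layer; the
multilayer and between_layer pipelines report nodal measures (and their
layer averages), since their global values mix all layers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import measures as gm
from .containers import (
    AtlasMetadata,
    ConnectivityMatrix,
    DensityGrid,
    LaminarTimeSeries,
)
from .networks import (
    build_layer_by_layer,
    build_multilayer,
    extract_between_layer,
    extract_within_layer,
    normalize_weights,
    threshold_proportional,
)
from .preprocess import FilterSpec, detrend_and_bandpass
from .similarity import edge_dispersion, method_similarity_curves
from .stats import compare_layers, tabulate_regions, thickness_confound_test
from .synthetic import EffectSpec, generate_atlas, generate_cohort

logger = logging.getLogger("laminarnet")

ALL_PIPELINES = ("layer_by_layer", "multilayer", "within_layer", "between_layer")


def _roi_of(labels: Sequence[tuple[int, int]]) -> np.ndarray:
    return np.array([r for r, _ in labels])


def _depth_of(labels: Sequence[tuple[int, int]]) -> np.ndarray:
    return np.array([d for _, d in labels])


def participant_auc_tables(
    ts: LaminarTimeSeries,
    pipelines: Iterable[str] = ALL_PIPELINES,
    grid: DensityGrid = DensityGrid(),
    filter_spec: FilterSpec | None = FilterSpec(),
    global_measures: Sequence[str] = gm.FAST_GLOBAL,
    nodal_measures: Sequence[str] = gm.FAST_NODAL,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute AUC tables for one participant across requested pipelines.

    ``filter_spec=None`` skips conditioning (for already-filtered input).
    """
    pipelines = tuple(pipelines)
    unknown = set(pipelines) - set(ALL_PIPELINES)
    if unknown:
        raise ValueError(f"unknown pipelines: {sorted(unknown)}")
    if filter_spec is not None:
        ts = detrend_and_bandpass(ts, filter_spec)
    g = len(grid)
    grid_x = grid.as_array()
    global_rows: list[dict] = []
    nodal_rows: list[dict] = []

    def emit(pipeline: str, layer: int, labels, acc_global, acc_nodal) -> None:
        """Integrate accumulated per-density values into AUC rows."""
        for m, vals in acc_global.items():
            global_rows.append(
                {
                    "participant": ts.participant_id,
                    "pipeline": pipeline,
                    "layer": layer,
                    "measure": m,
                    "auc": float(np.trapezoid(np.nan_to_num(vals), x=grid_x)),
                }
            )
        rois = _roi_of(labels)
        for m, vals in acc_nodal.items():
            aucs = np.trapezoid(vals, x=grid_x, axis=0)
            global_rows.append(
                {
                    "participant": ts.participant_id,
                    "pipeline": pipeline,
                    "layer": layer,
                    "measure": f"avg_{m}",
                    "auc": float(aucs.mean()),
                }
            )
            for roi, auc in zip(rois, aucs):
                nodal_rows.append(
                    {
                        "participant": ts.participant_id,
                        "pipeline": pipeline,
                        "layer": layer,
                        "measure": m,
                        "node": int(roi),
                        "auc": float(auc),
                    }
                )

    if "layer_by_layer" in pipelines:
        for cm in build_layer_by_layer(ts):
            depth = cm.node_labels[0][1]
            norm = normalize_weights(cm)
            acc_g = {m: np.zeros(g) for m in global_measures}
            acc_n = {m: np.zeros((g, norm.n_nodes)) for m in nodal_measures}
            for gi, density in enumerate(grid.values):
                thr = threshold_proportional(norm, density)
                summ = gm.graph_summary(
                    thr.weights, global_measures, nodal_measures, seed=seed
                )
                for m in global_measures:
                    acc_g[m][gi] = summ[m]
                for m in nodal_measures:
                    acc_n[m][gi] = summ[m]
            emit("layer_by_layer", depth, norm.node_labels, acc_g, acc_n)

    family = [p for p in pipelines if p != "layer_by_layer"]
    if family:
        ml = normalize_weights(build_multilayer(ts))
        depths = ml.depths
        depth_arr = _depth_of(ml.node_labels)
        acc: dict[str, dict] = {}
        if "within_layer" in family:
            acc["within"] = {
                d: (
                    {m: np.zeros(g) for m in global_measures},
                    {m: np.zeros((g, len(ml.layer_index(d)))) for m in nodal_measures},
                )
                for d in depths
            }
        for tag in ("multilayer", "between_layer"):
            if tag in family:
                acc[tag] = {m: np.zeros((g, ml.n_nodes)) for m in nodal_measures}
        for gi, density in enumerate(grid.values):
            thr = threshold_proportional(ml, density)
            if "within_layer" in family:
                for d in depths:
                    block = extract_within_layer(thr, d)
                    summ = gm.graph_summary(
                        block.weights, global_measures, nodal_measures, seed=seed
                    )
                    acc_g, acc_n = acc["within"][d]
                    for m in global_measures:
                        acc_g[m][gi] = summ[m]
                    for m in nodal_measures:
                        acc_n[m][gi] = summ[m]
            if "multilayer" in family:
                summ = gm.graph_summary(thr.weights, (), nodal_measures, seed=seed)
                for m in nodal_measures:
                    acc["multilayer"][m][gi] = summ[m]
            if "between_layer" in family:
                btw = extract_between_layer(thr)
                summ = gm.graph_summary(btw.weights, (), nodal_measures, seed=seed)
                for m in nodal_measures:
                    acc["between_layer"][m][gi] = summ[m]
        if "within_layer" in family:
            for d in depths:
                labels = tuple(ml.node_labels[i] for i in ml.layer_index(d))
                acc_g, acc_n = acc["within"][d]
                emit("within_layer", d, labels, acc_g, acc_n)
        for tag in ("multilayer", "between_layer"):
            if tag in family:
                for d in depths:
                    idx = np.flatnonzero(depth_arr == d)
                    labels = tuple(ml.node_labels[i] for i in idx)
                    acc_n = {m: acc[tag][m][:, idx] for m in nodal_measures}
                    emit(tag, d, labels, {}, acc_n)
    return pd.DataFrame(global_rows), pd.DataFrame(nodal_rows)


def cohort_auc_tables(
    cohort: Sequence[LaminarTimeSeries], **kwargs
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenate participant AUC tables over a cohort."""
    gtabs, ntabs = [], []
    for ts in cohort:
        gt, nt = participant_auc_tables(ts, **kwargs)
        gtabs.append(gt)
        ntabs.append(nt)
    return (
        pd.concat(gtabs, ignore_index=True),
        pd.concat(ntabs, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# configuration and orchestration


@dataclass
class PipelineConfig:
    """Config for the end-to-end runner (YAML/JSON loadable)."""

    output_dir: str = "laminarnet_out"
    cohort_manifest: str | None = None  # JSON manifest of participant TSVs
    atlas_path: str | None = None
    tr_seconds: float = 2.8
    # synthetic mode (used when cohort_manifest is None)
    n_participants: int = 10
    n_roi: int = 40
    n_depths: int = 3
    n_timepoints: int = 400
    effect: EffectSpec = field(default_factory=EffectSpec)
    share_structure: bool = True
    # analysis
    grid: DensityGrid = field(default_factory=DensityGrid)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    pipelines: tuple[str, ...] = ALL_PIPELINES
    global_measures: tuple[str, ...] = gm.FAST_GLOBAL
    nodal_measures: tuple[str, ...] = gm.FAST_NODAL
    dispersion_fraction: float = 0.05
    global_alpha: float = 0.05
    nodal_alpha: float = 0.01
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "effect" in raw:
            raw["effect"] = EffectSpec(**raw["effect"])
        if "grid" in raw:
            raw["grid"] = DensityGrid(tuple(raw["grid"]))
        if "filter_spec" in raw:
            raw["filter_spec"] = FilterSpec(**raw["filter_spec"])
        for key in ("pipelines", "global_measures", "nodal_measures"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: repr(v) for k, v in sorted(self.__dict__.items())}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_cohort(
    manifest_path: str | Path, tr_seconds: float
) -> list[LaminarTimeSeries]:
    """Load participant time series from a JSON manifest of TSV paths."""
    manifest = json.loads(Path(manifest_path).read_text())
    base = Path(manifest_path).parent
    cohort = []
    for entry in manifest["participants"]:
        path = base / entry["path"]
        cohort.append(
            LaminarTimeSeries.from_tsv(
                path,
                tr_seconds=manifest.get("tr_seconds", tr_seconds),
                participant_id=entry.get("id"),
            )
        )
    return cohort


def run_pipeline(config: PipelineConfig) -> dict:
    """Run synth (optional) -> preprocess -> construct -> measure -> stats.

    Writes long-format TSV tables and a JSON summary under
    ``config.output_dir`` and returns the in-memory results.
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logger.info("run %s starting (seed=%d)", chash, config.seed)

    if config.cohort_manifest is None:
        atlas = generate_atlas(config.n_roi, seed=config.seed)
        cohort = generate_cohort(
            atlas,
            config.n_participants,
            config.n_depths,
            config.n_timepoints,
            config.tr_seconds,
            config.effect,
            seed=config.seed,
            share_structure=config.share_structure,
        )
        atlas.to_tsv(out / "atlas.tsv")
    else:
        atlas = AtlasMetadata.from_tsv(config.atlas_path)
        cohort = load_cohort(config.cohort_manifest, config.tr_seconds)
    logger.info("cohort: %d participants", len(cohort))

    conditioned = [detrend_and_bandpass(ts, config.filter_spec) for ts in cohort]

    # edge dispersion on raw multilayer matrices
    raw_ml = [build_multilayer(ts) for ts in conditioned]
    dispersion = {
        mode: edge_dispersion(raw_ml, mode, config.dispersion_fraction)
        for mode in ("consistency", "variability")
    }
    for mode, blocks in dispersion.items():
        pd.DataFrame(
            [
                {"layer_i": a, "layer_j": b, "pct": pct}
                for (a, b), pct in blocks.block_pct.items()
            ]
        ).to_csv(out / f"edge_{mode}_blocks.tsv", sep="\t", index=False)

    # method similarity (layer-by-layer vs within-layer) per participant
    sim_rows = []
    for ts, ml in zip(conditioned, raw_ml):
        lbl = [normalize_weights(cm) for cm in build_layer_by_layer(ts)]
        curves = method_similarity_curves(lbl, normalize_weights(ml), config.grid)
        for d, curve in curves.items():
            sim_rows.append(
                {
                    "participant": ts.participant_id,
                    "layer": d,
                    "auc": curve.auc,
                }
            )
    sim_table = pd.DataFrame(sim_rows)
    sim_table.to_csv(out / "method_similarity_auc.tsv", sep="\t", index=False)

    global_tab, nodal_tab = cohort_auc_tables(
        conditioned,
        pipelines=config.pipelines,
        grid=config.grid,
        filter_spec=None,
        global_measures=config.global_measures,
        nodal_measures=config.nodal_measures,
        seed=config.seed,
    )
    global_tab.to_csv(out / "auc_global.tsv", sep="\t", index=False)
    nodal_tab.to_csv(out / "auc_nodal.tsv", sep="\t", index=False)

    results = {"dispersion": dispersion, "similarity": sim_table}
    stats_rows, region_tabs, thickness_rows = [], [], []
    peak_grid = {}
    for pipeline in config.pipelines:
        gsub = global_tab[global_tab["pipeline"] == pipeline]
        if not gsub.empty:
            gres = compare_layers(
                gsub, scope="global", alpha=config.global_alpha
            )
            gres.insert(0, "pipeline", pipeline)
            stats_rows.append(gres)
            peak_grid[pipeline] = {
                row["measure"]: int(row["peak_layer"])
                for _, row in gres.iterrows()
                if row["significant"]
            }
        nsub = nodal_tab[nodal_tab["pipeline"] == pipeline]
        if not nsub.empty:
            nres = compare_layers(nsub, scope="nodal", alpha=config.nodal_alpha)
            nres.insert(0, "pipeline", pipeline)
            stats_rows.append(nres)
            regions = tabulate_regions(nres, atlas)
            regions.insert(0, "pipeline", pipeline)
            region_tabs.append(regions)
            thick = thickness_confound_test(nres, atlas)
            thick.insert(0, "pipeline", pipeline)
            thickness_rows.append(thick)
    stats_table = pd.concat(stats_rows, ignore_index=True)
    stats_table.to_csv(out / "layer_comparisons.tsv", sep="\t", index=False)
    region_table = pd.concat(region_tabs, ignore_index=True)
    region_table.to_csv(out / "significant_regions.tsv", sep="\t", index=False)
    thickness_table = pd.concat(thickness_rows, ignore_index=True)
    thickness_table.to_csv(out / "thickness_confound.tsv", sep="\t", index=False)

    summary = {
        "config_hash": chash,
        "seed": config.seed,
        "n_participants": len(cohort),
        "n_roi": atlas.n_roi,
        "n_depths": conditioned[0].n_depths,
        "n_timepoints": conditioned[0].n_timepoints,
        "supra_matrix_size": raw_ml[0].n_nodes,
        "n_densities": len(config.grid),
        "peak_layers_significant": peak_grid,
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
    results.update(
        {
            "atlas": atlas,
            "global_auc": global_tab,
            "nodal_auc": nodal_tab,
            "stats": stats_table,
            "regions": region_table,
            "thickness": thickness_table,
            "summary": summary,
        }
    )
    logger.info("run %s finished in %.1fs", chash, summary["elapsed_seconds"])
    return results


FIXTURE_SCALES = {
    "tiny": dict(n_participants=4, n_roi=10, n_depths=2, n_timepoints=120),
    "demo": dict(n_participants=10, n_roi=40, n_depths=3, n_timepoints=400),
    "full": dict(n_participants=30, n_roi=148, n_depths=5, n_timepoints=2028),
}


def make_fixtures(scale: str, seed: int, outdir: str | Path) -> Path:
    """Write a deterministic cohort + atlas + config under ``outdir``."""
    if scale not in FIXTURE_SCALES:
        raise ValueError(f"scale must be one of {sorted(FIXTURE_SCALES)}")
    params = FIXTURE_SCALES[scale]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    atlas = generate_atlas(params["n_roi"], seed=seed)
    atlas.to_tsv(outdir / "atlas.tsv")
    cohort = generate_cohort(
        atlas,
        params["n_participants"],
        params["n_depths"],
        params["n_timepoints"],
        2.8,
        EffectSpec(),
        seed=seed,
    )
    entries = []
    for ts in cohort:
        fname = f"{ts.participant_id}.tsv"
        ts.to_tsv(outdir / fname)
        entries.append({"id": ts.participant_id, "path": fname})
    (outdir / "manifest.json").write_text(
        json.dumps({"tr_seconds": 2.8, "participants": entries}, indent=2)
    )
    config = {
        "cohort_manifest": str(outdir / "manifest.json"),
        "atlas_path": str(outdir / "atlas.tsv"),
        "output_dir": str(outdir / "results"),
        "seed": seed,
    }
    (outdir / "config.yaml").write_text(yaml.safe_dump(config))
    return outdir
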