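"""Core data containers shared by every pipeline stage.

Node ordering convention
------------------------
Depth-resolved channels are ordered depth-major: the first R channels are
all ROIs at depth 1 (the most superficial depth), the next R at depth 2,
and so on.  In the supra-adjacency matrix of the multilayer network this
means nodes ``0..R-1`` form layer 1, ``R..2R-1`` layer 2, etc.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

REGIONS = ("frontal", "limbic", "occipital", "parietal", "temporal", "insula")
HEMISPHERES = ("left", "right")

PIPELINE_TAGS = ("layer_by_layer", "multilayer", "within_layer", "between_layer")


@dataclass(frozen=True)
class AtlasMetadata:
    """Per-ROI parcellation metadata: hemisphere, region group, thickness.

    Defines the canonical node ordering (by ``roi_id``) used by every
    downstream matrix.
    """

    table: pd.DataFrame  # columns: roi_id, name, hemisphere, region, thickness_mm

    def __post_init__(self) -> None:
        required = {"roi_id", "name", "hemisphere", "region", "thickness_mm"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        ids = self.table["roi_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("roi_id values must be unique")
        if not np.array_equal(np.sort(ids), np.arange(len(ids))):
            raise ValueError("roi_id values must be 0..R-1")
        if (self.table["thickness_mm"] <= 0).any():
            raise ValueError("thickness_mm must be positive")
        bad_hemi = set(self.table["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValueError(f"unknown hemisphere labels: {bad_hemi}")
        bad_region = set(self.table["region"]) - set(REGIONS)
        if bad_region:
            raise ValueError(f"unknown region labels: {bad_region}")

    @property
    def n_roi(self) -> int:
        return len(self.table)

    def thickness(self) -> np.ndarray:
        """Thickness (mm) ordered by roi_id."""
        return (
            self.table.sort_values("roi_id")["thickness_mm"].to_numpy(dtype=float)
        )

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AtlasMetadata":
        return cls(pd.read_csv(path, sep="\t"))


def channel_labels(n_roi: int, n_depths: int) -> list[tuple[int, int]]:
    """Depth-major (roi_id, depth) channel labels; depth 1 = most superficial."""
    return [(r, d) for d in range(1, n_depths + 1) for r in range(n_roi)]


@dataclass(frozen=True)
class LaminarTimeSeries:
    """One participant's depth-resolved ROI time series.

    ``data`` is T x (R*D); columns follow :func:`channel_labels` ordering.
    """

    participant_id: str
    data: np.ndarray
    channel_labels: tuple[tuple[int, int], ...]
    tr_seconds: float

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (time x channels)")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 time points")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel count must match channel_labels")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_roi(self) -> int:
        return len({r for r, _ in self.channel_labels})

    @property
    def n_depths(self) -> int:
        return len({d for _, d in self.channel_labels})

    @property
    def sampling_hz(self) -> float:
        return 1.0 / self.tr_seconds

    def to_tsv(self, path: str | Path) -> None:
        cols = [f"roi{r}_depth{d}" for r, d in self.channel_labels]
        pd.DataFrame(self.data, columns=cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, tr_seconds: float, participant_id: str | None = None
    ) -> "LaminarTimeSeries":
        df = pd.read_csv(path, sep="\t")
        labels = []
        for col in df.columns:
            roi_part, depth_part = col.split("_")
            labels.append((int(roi_part[3:]), int(depth_part[5:])))
        return cls(
            participant_id=participant_id or Path(path).stem,
            data=df.to_numpy(dtype=float),
            channel_labels=tuple(labels),
            tr_seconds=tr_seconds,
        )


@dataclass
class ConnectivityMatrix:
    """Square symmetric weighted matrix with layer-tagged node labels."""

    weights: np.ndarray
    node_labels: tuple[tuple[int, int], ...]
    pipeline_tag: str
    density: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if w.shape[0] != len(self.node_labels):
            raise ValueError("node_labels length must match matrix size")
        if self.pipeline_tag not in PIPELINE_TAGS:
            raise ValueError(f"pipeline_tag must be one of {PIPELINE_TAGS}")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if np.abs(np.diag(w)).max(initial=0.0) > 1e-12:
            raise ValueError("diagonal must be zero")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def depths(self) -> tuple[int, ...]:
        return tuple(sorted({d for _, d in self.node_labels}))

    def realized_density(self) -> float:
        n = self.n_nodes
        edges = np.count_nonzero(np.triu(self.weights, 1))
        return edges / (n * (n - 1) / 2)

    def layer_index(self, depth: int) -> np.ndarray:
        """Node indices belonging to one depth, in roi order."""
        idx = [i for i, (_, d) in enumerate(self.node_labels) if d == depth]
        if not idx:
            raise ValueError(f"no nodes at depth {depth}")
        return np.asarray(idx)

    def to_tsv(self, path: str | Path) -> None:
        cols = [f"roi{r}_depth{d}" for r, d in self.node_labels]
        pd.DataFrame(self.weights, columns=cols).to_csv(path, sep="\t", index=False)
        sidecar = Path(path).with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "pipeline_tag": self.pipeline_tag,
                    "density": self.density,
                    "realized_density": self.realized_density(),
                }
            )
        )


@dataclass(frozen=True)
class DensityGrid:
    """Proportional-threshold density grid; default 2%..40% in 2% steps."""

    values: tuple[float, ...] = tuple(np.round(np.arange(0.02, 0.41, 0.02), 2))

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) < 1:
            raise ValueError("grid must be a non-empty 1-D sequence")
        if not np.all(np.diff(v) > 0):
            raise ValueError("grid must be strictly increasing")
        if v[0] <= 0 or v[-1] > 1:
            raise ValueError("grid values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass
class MeasureCurve:
    """A graph measure evaluated along the density grid plus its AUC."""

    measure_name: str
    scope: str  # "global" | "nodal"
    values: np.ndarray  # (G,) for global, (G, N) for nodal
    grid: DensityGrid
    auc: float | np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scope not in ("global", "nodal"):
            raise ValueError("scope must be 'global' or 'nodal'")
        if self.values.shape[0] != len(self.grid):
            raise ValueError("values length must equal grid length")
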