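"""Synthetic depth-resolved resting-state cohorts with planted laminar structure.

The generator is a latent-factor linear-Gaussian model, not a hemodynamic
simulator: each ROI at each depth carries a latent Gaussian factor, planted
within-layer connectivity mixes neighbouring factors, a venous-drainage-like
leakage term mixes deeper signal into shallower depths, and observation
noise is added per participant.  The planted graph and latent factors are
shared across a cohort (the "anatomy"), while observation noise is
independent per participant — so group statistics see the layers as repeated
measures of one planted connectome.

Planted within-layer edge probability at depth ``d`` (1 = superficial) is

    p_d = edge_prob_base * (1 + density_gradient * (1 - 2*(d-1)/(D-1)))

so a positive ``density_gradient`` makes superficial layers denser, the
direction reported for gradient-echo laminar BOLD (pial-vein bias).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import (
    REGIONS,
    AtlasMetadata,
    LaminarTimeSeries,
    channel_labels,
)

import pandas as pd

# Destrieux-like per-hemisphere region counts (sum 74); insula ROIs are
# folded into the five named groups in the reference grouping, so its
# default share is zero.
_REGION_COUNTS_74 = {
    "frontal": 24,
    "temporal": 16,
    "limbic": 14,
    "occipital": 10,
    "parietal": 10,
    "insula": 0,
}

THICKNESS_MEAN_MM = 2.4
THICKNESS_SD_MM = 0.25
THICKNESS_CLIP_MM = (1.0, 4.5)


@dataclass(frozen=True)
class EffectSpec:
    """Knobs of the planted laminar effect.

    density_gradient : monotone change of within-layer edge density from the
        superficial to the deep layer, in [-1, 1]; 0 gives the exchangeable
        null model.
    leakage_lambda : fraction of the mean strictly-deeper signal mixed into
        each shallower depth, in [0, 1).
    noise_sd : per-participant additive Gaussian observation noise.
    edge_prob_base : baseline within-layer edge probability, in (0, 1).
    effect_strength : scaling of planted neighbour mixing (edge correlation
        strength).
    """

    density_gradient: float = 0.0
    leakage_lambda: float = 0.0
    noise_sd: float = 1.0
    edge_prob_base: float = 0.15
    effect_strength: float = 1.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.density_gradient <= 1.0:
            raise ValueError("density_gradient must be in [-1, 1]")
        if not 0.0 <= self.leakage_lambda < 1.0:
            raise ValueError("leakage_lambda must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 < self.edge_prob_base < 1.0:
            raise ValueError("edge_prob_base must be in (0, 1)")
        if self.effect_strength < 0:
            raise ValueError("effect_strength must be non-negative")


#: Planted-gradient conditions used throughout the docs and simulations:
#: superficial layers roughly twice as densely connected as deep ones, with
#: clearly supra-noise edge correlations.
PLANTED_EFFECT = EffectSpec(
    density_gradient=0.5,
    leakage_lambda=0.2,
    noise_sd=1.0,
    edge_prob_base=0.15,
    effect_strength=1.0,
)

#: Exchangeable-layers null: no gradient, no leakage.
NULL_EFFECT = EffectSpec(
    density_gradient=0.0,
    leakage_lambda=0.0,
    noise_sd=1.0,
    edge_prob_base=0.15,
    effect_strength=1.0,
)


def _region_allocation(per_hemi: int) -> list[str]:
    """Largest-remainder allocation of region labels for one hemisphere."""
    total = sum(_REGION_COUNTS_74.values())
    quotas = {r: per_hemi * c / total for r, c in _REGION_COUNTS_74.items()}
    counts = {r: int(np.floor(q)) for r, q in quotas.items()}
    leftover = per_hemi - sum(counts.values())
    order = sorted(
        _REGION_COUNTS_74, key=lambda r: (-(quotas[r] - counts[r]), r)
    )
    for r in order[:leftover]:
        counts[r] += 1
    labels: list[str] = []
    for region in REGIONS:
        labels.extend([region] * counts.get(region, 0))
    return labels


def generate_atlas(n_roi: int, seed: int) -> AtlasMetadata:
    """Generate Destrieux-like parcellation metadata.

    ROIs alternate between hemispheres is not required; instead the first
    half is left, second half right (n_roi/2 each).  Thickness is drawn from
    a clipped normal around 2.4 mm.  Deterministic given ``seed``.
    """
    if n_roi % 2 != 0 or n_roi < 4:
        raise ValueError("n_roi must be even and >= 4")
    rng = np.random.default_rng(seed)
    per_hemi = n_roi // 2
    regions = _region_allocation(per_hemi) * 2
    hemis = ["left"] * per_hemi + ["right"] * per_hemi
    thickness = rng.normal(THICKNESS_MEAN_MM, THICKNESS_SD_MM, size=n_roi)
    thickness = np.clip(thickness, *THICKNESS_CLIP_MM)
    table = pd.DataFrame(
        {
            "roi_id": np.arange(n_roi),
            "name": [
                f"{h[0].upper()}_{reg}_{i}" for i, (h, reg) in enumerate(zip(hemis, regions))
            ],
            "hemisphere": hemis,
            "region": regions,
            "thickness_mm": thickness,
        }
    )
    return AtlasMetadata(table)


@dataclass(frozen=True)
class PlantedStructure:
    """Shared cohort structure: planted graphs per depth + latent signals."""

    adjacency: tuple[np.ndarray, ...]  # D binary R x R matrices
    signals: np.ndarray  # T x (R*D), depth-major, leakage already applied


def layer_edge_probability(effect: EffectSpec, depth: int, n_depths: int) -> float:
    """Planted within-layer edge probability at ``depth`` (1-based)."""
    if n_depths == 1:
        frac = 0.0
    else:
        frac = 1.0 - 2.0 * (depth - 1) / (n_depths - 1)
    p = effect.edge_prob_base * (1.0 + effect.density_gradient * frac)
    return float(np.clip(p, 0.0, 1.0))


def plant_structure(
    n_roi: int,
    n_depths: int,
    n_timepoints: int,
    effect: EffectSpec,
    seed: int | np.random.SeedSequence,
) -> PlantedStructure:
    """Draw the cohort-shared planted graphs and latent depth signals."""
    rng = np.random.default_rng(seed)
    adjacency = []
    signal_blocks = []
    for d in range(1, n_depths + 1):
        p = layer_edge_probability(effect, d, n_depths)
        upper = rng.random((n_roi, n_roi)) < p
        A = np.triu(upper, 1)
        A = (A | A.T).astype(float)
        adjacency.append(A)
        Z = rng.standard_normal((n_timepoints, n_roi))
        S = Z + effect.effect_strength * (Z @ A)
        signal_blocks.append(S)
    # leakage: strictly deeper -> shallower, per ROI; deepest untouched
    leaked = []
    for d in range(n_depths):
        S = signal_blocks[d].copy()
        deeper = signal_blocks[d + 1 :]
        if deeper and effect.leakage_lambda > 0:
            S = S + effect.leakage_lambda * np.mean(deeper, axis=0)
        leaked.append(S)
    signals = np.concatenate(leaked, axis=1)
    return PlantedStructure(adjacency=tuple(adjacency), signals=signals)


def generate_participant(
    atlas: AtlasMetadata,
    n_depths: int,
    n_timepoints: int,
    tr_seconds: float,
    effect: EffectSpec,
    seed: int | np.random.SeedSequence,
    structure: PlantedStructure | None = None,
    participant_id: str = "sub-01",
) -> LaminarTimeSeries:
    """Generate one participant's depth-resolved time series.

    When ``structure`` is omitted it is derived deterministically from
    ``seed`` (both the planted structure and the observation noise), so the
    function is a pure function of its arguments.
    """
    if n_depths < 2:
        raise ValueError("n_depths must be >= 2")
    if n_timepoints < 10 * atlas.n_roi:
        raise ValueError(
            "n_timepoints must be >= 10x the number of planted latent factors "
            f"({10 * atlas.n_roi} for {atlas.n_roi} ROIs)"
        )
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    structure_ss, noise_ss = ss.spawn(2)
    if structure is None:
        structure = plant_structure(
            atlas.n_roi, n_depths, n_timepoints, effect, structure_ss
        )
    noise_rng = np.random.default_rng(noise_ss)
    data = structure.signals + effect.noise_sd * noise_rng.standard_normal(
        structure.signals.shape
    )
    return LaminarTimeSeries(
        participant_id=participant_id,
        data=data,
        channel_labels=tuple(channel_labels(atlas.n_roi, n_depths)),
        tr_seconds=tr_seconds,
    )


def generate_cohort(
    atlas: AtlasMetadata,
    n_participants: int,
    n_depths: int,
    n_timepoints: int,
    tr_seconds: float,
    effect: EffectSpec,
    seed: int,
    share_structure: bool = True,
) -> list[LaminarTimeSeries]:
    """Generate a cohort of participants with planted laminar structure.

    Participant seeds are derived deterministically from the master seed.
    With ``share_structure=True`` (default) the planted graph topology and
    latent factors are common to all participants and only observation
    noise differs — a repeated-measures view of one connectome.  With
    ``share_structure=False`` every participant draws an independent
    planted realization of the same effect parameters, which is the
    sampling model under which layer ANOVAs across participants are
    calibrated (independent participants).
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    master = np.random.SeedSequence(seed)
    structure_ss, *participant_ss = master.spawn(n_participants + 1)
    structure = (
        plant_structure(atlas.n_roi, n_depths, n_timepoints, effect, structure_ss)
        if share_structure
        else None
    )
    cohort = []
    for i, pss in enumerate(participant_ss):
        cohort.append(
            generate_participant(
                atlas,
                n_depths,
                n_timepoints,
                tr_seconds,
                effect,
                pss,
                structure=structure,
                participant_id=f"sub-{i + 1:02d}",
            )
        )
    return cohort
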