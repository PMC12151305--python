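# Methods

This note documents the models, conventions and numerical choices behind
`laminarnet`, in the order the pipeline applies them.

## Synthetic laminar cohorts

The generator is a latent-factor linear-Gaussian model, chosen for a
tractable, known covariance structure rather than hemodynamic realism: the
package's claims are about recovery of planted network structure, not about
BOLD biophysics.

For each depth *d* (1 = most superficial of *D*), an Erdős–Rényi graph over
the *R* ROIs is planted with edge probability

    p_d = edge_prob_base · (1 + density_gradient · (1 − 2(d−1)/(D−1))),

clipped to [0, 1].  A positive `density_gradient` therefore makes
superficial layers denser — the direction expected from pial-vein
(draining-vein) bias in gradient-echo laminar BOLD.  Each (ROI, depth)
channel carries a standard-normal latent factor time series Z; the planted
signal is S = Z + effect_strength · Z·A_d, so planted neighbours share
variance.  Superficial-ward leakage adds `leakage_lambda` times the mean of
all strictly deeper same-ROI signals to each channel (the deepest layer
receives none), emulating venous drainage direction.  Per-participant
observation noise is iid Gaussian with `noise_sd`.

Defaults (module constants, used by all documented simulations):

| parameter | null model | planted model | meaning |
|---|---|---|---|
| `edge_prob_base` | 0.15 | 0.15 | baseline within-layer edge probability |
| `density_gradient` | 0 | 0.5 | superficial layers ~2× denser than deep |
| `leakage_lambda` | 0 | 0.2 | deeper-signal fraction mixed superficially |
| `noise_sd` | 1.0 | 1.0 | observation noise (latent signals have unit scale) |
| `effect_strength` | 1.0 | 1.0 | planted edge-correlation strength |

Atlas metadata mimics a Destrieux-scale parcellation: hemispheres split
R/2–R/2, region groups allocated by largest-remainder scaling of the
per-hemisphere reference counts (frontal 24, temporal 16, limbic 14,
occipital 10, parietal 10 of 74), and thickness drawn from a normal
(mean 2.4 mm, sd 0.25 mm) clipped to [1.0, 4.5] mm.  All generators are
pure functions of their seed via `numpy` `SeedSequence` spawning.

**Two sampling views.**  `generate_cohort(share_structure=True)` (default)
shares the planted graphs and latent factors across participants, so the
cohort is a repeated-measures sample of one connectome — useful for
determinism contracts and dispersion analyses.  With
`share_structure=False` each participant draws an independent planted
realization of the same effect parameters.  The distinction matters
statistically: a one-way ANOVA across layers treats participants as
independent samples, and conditioning on a single shared realized
connectome makes the layer comparison anti-conservative (between-layer
variance then contains graph-realization variance that within-layer
variance lacks).  All Monte-Carlo calibration therefore uses
`share_structure=False`.

What the generator does **not** emulate: hemodynamic response shape and
autocorrelation, physiological noise structure, motion, spatially smooth
signal leakage (leakage here is strictly per-ROI and strictly
deeper→shallower), inter-individual topology variation beyond independent
redraws, and depth-dependent tSNR.  Passing tests show the pipeline
recovers planted covariance structure under Gaussian noise — not that any
particular biological claim holds in real laminar fMRI.  One consequence:
the method-similarity (layer-by-layer vs within-layer) AUC rises
monotonically with depth under leakage in this generator, rather than
peaking at mid-depths.

## Conditioning

Runs are concatenated first, then each channel is linearly detrended and
band-pass filtered (Butterworth, design order 2 before the
forward–backward pass, 0.01–0.1 Hz by default) with `sosfiltfilt` and
reflective padding of 3·order samples, bounding edge transients on short
runs at the cost of small residual means near the boundaries.  "Order" is
the design order; the zero-phase pass doubles the effective roll-off, and
the measured amplitude response equals |H(f)|².

## Network construction

Pearson correlations are Fisher z-transformed with |r| clamped at 1 − 1e−7
so perfectly correlated channels keep a finite weight.  Normalization
zeroes negative weights and rescales by the maximum weight (max → 1), the
standard weight-conversion convention for weighted graph analysis; it makes
within/between-layer extraction scale-consistent.  Proportional
thresholding retains the k = round(density · N(N−1)/2) largest positive
weights (round half away from zero; ties broken by ascending (i, j) index
for reproducibility).  If fewer positive weights exist, all are kept and
the realized density recorded.  Layer-by-layer matrices are thresholded
independently to the same target density, which is why density and average
degree carry no information in that pipeline; within-layer blocks extracted
from the jointly thresholded supra matrix inherit unequal layer-wise
densities, which is exactly where a planted density gradient becomes
visible.

The thresholded supra matrix decomposes exactly as the sum of its embedded
within-layer blocks plus the between-layer remainder; this identity is
enforced by construction and tested on random instances.

## Graph measures

Weighted variants are used throughout, with the conventions standard in
connectomics toolboxes: shortest-path lengths on 1/weight; characteristic
path length averages finite distances only; global efficiency counts
disconnected pairs as zero; radius/diameter and eigenvector centrality are
computed on the largest connected component (zeros elsewhere), because
low-density thresholds disconnect graphs and the profiles must remain
defined along the whole grid.  Clustering uses the geometric mean of
triangle weights, C_i = (W^{1/3})³_ii / (k_i(k_i−1)) with binary degree k,
assuming weights in [0, 1] (guaranteed after normalization); transitivity
is the matching closed-triple ratio; local efficiency is the global
efficiency of each node's neighbourhood subgraph.  Betweenness uses
unnormalized Brandes counts with endpoints excluded.  Modularity is
Louvain at resolution γ = 1, best of 10 seeded restarts; the participation
coefficient is computed against that same partition, since the analysis
needs one community assignment per thresholded graph.  Assortativity is
Newman's symmetric weighted-degree formula and returns NaN on regular
graphs (zero endpoint-degree variance).  Small-world σ uses degree-
preserving edge swaps (weights follow edges, 10 swap attempts per edge,
100 nulls by default, seeded) and null statistics averaged before the
ratio.  Eigenvector centrality is computed by direct symmetric
eigendecomposition, so no iterative-convergence failure mode exists.

AUC summaries use the trapezoidal rule over the density grid expressed as
fractions (0.02…0.40); the rule is exact on linear curves, and the
constant-2 curve integrates to 2 × 0.38 = 0.76.  NaN values (undefined
assortativity at sparse densities) are treated as 0 when integrating a
global curve.

## Edge dispersion and similarity

Edge consistency/variability is computed on the raw (unthresholded,
unnormalized) Fisher-z supra matrices: per-edge standard deviation across
participants (ddof = 1), selection of floor(0.05 · E) edges at the stated
extreme with index-order tie-breaking, tabulated per layer-pair block.
Per-layer totals assign within-layer blocks fully and split between-layer
blocks half to each participating layer, the only aggregation under which
the per-layer totals sum to 100 %.  Cosine similarity compares
upper-triangular weight vectors and returns NaN for an all-zero matrix.

## Layer statistics

One-way ANOVA is implemented directly (classical sums of squares) so that
degenerate inputs have defined behaviour: observations identical up to
floating-point arithmetic (within 1e−12 of the data's squared magnitude)
give F = 0, p = 1; zero within-group variance with unequal means gives the
(∞, 0) sentinel with a warning.  Global measures (including layer-averaged
nodal measures, reported as `avg_<measure>`) are corrected across measures
with Benjamini–Hochberg at α = 0.05; individual nodal measures across ROIs
within each measure with Holm step-down at α = 0.01.  For the multilayer
and between-layer pipelines only nodal measures are compared (their global
values mix all layers), with each ROI's D depth copies as the ANOVA
groups.  Peak layer is the argmax of group-mean AUC, ties to the lowest
(most superficial) layer index.  The thickness confound test is a pooled
two-sample t test of mean ROI thickness, significant vs nonsignificant
nodes, run only when more than 10 nodes are significant.  ANOVA normality
and equal-variance assumptions are not enforced; network-measure AUCs can
violate them, which is a known caveat of this design.

## Simulation scale

The standing Monte-Carlo experiments use 20 cohorts of 10 participants,
40 ROIs, 3 depths and T = 400 (TR 2.8 s) — large enough for the planted
gradient to be unambiguous and for the binomial envelope around α to be
informative, small enough to run routinely.  Their measure suite is the
closed-form set (composition, distances, clustering/local efficiency,
eigenvector, betweenness, assortativity); Louvain modularity,
participation and small-world σ are excluded from the repeated
simulations because their per-graph cost multiplies across
participants × layers × 20 densities, and their correctness is covered by
the exhaustive small-graph oracle suite instead.

## Known limitations

* The generator's exchangeable-null calibration covers the statistics, not
  ANOVA robustness to the heavier-tailed AUC distributions of real data.
* "Normalization" conventions for multilayer matrices are genuinely open in
  the field; the max-rescaling choice here is documented and configurable,
  and layer-wise density differences should be interpreted in its light.
* No negative-weight network analysis and no inter-layer coupling
  parameter (the supra matrix is analysed as one static weighted graph).
* No partial-correlation construction.
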