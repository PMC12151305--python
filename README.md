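# laminarnet

Laminar multilayer functional connectomics: build depth-resolved functional
brain networks, profile weighted graph measures across proportional
thresholds, and test whether network organisation differs across cortical
depths.

## Who this is for

Laminar (sub-millimetre, depth-resolved) resting-state fMRI yields, for
each cortical region of interest (ROI), one time series per cortical depth.
`laminarnet` is for researchers who want to ask connectomic questions of
such data: does functional network topology change from the pial surface to
the white-matter boundary?  The package implements the full analysis chain
downstream of image preprocessing — it starts from delimited-text time
series (rows = time points, columns = ROI × depth channels) plus an atlas
metadata table, and ends at layer-comparison statistics.  A synthetic
cohort generator with planted laminar structure makes every stage testable
without any imaging data.

## The analysis

Two parallel network constructions are computed per participant from
detrended, band-pass-filtered (second-order zero-phase Butterworth,
0.01–0.1 Hz) time series:

* **Layer-by-layer** — Pearson correlations between ROIs within one depth,
  Fisher z-transformed: one *R* × *R* matrix per depth (for the Destrieux
  scale, R = 148 gives 10,878 unique pairs per matrix).
* **Multilayer** — correlations between all depth-resolved channels: one
  (*R·D*) × (*R·D*) supra-adjacency matrix in depth-major node order
  (148 × 5 = 740 nodes, 273,430 unique pairs).  After joint proportional
  thresholding, **within-layer** diagonal blocks and the **between-layer**
  remainder are extracted from it.

Matrices are normalized (negative weights zeroed, rescaled by the maximum)
and proportionally thresholded over a density grid of 2 %–40 % in 2 % steps.
Weighted graph measures — density, degree *k*, strength *s*, largest
cluster size, characteristic path length *L* and global efficiency on
1/w distances, radius/diameter, betweenness, eigenvector centrality,
geometric-mean clustering *C*, transitivity, local efficiency, Louvain
modularity *Q*, participation coefficient *P_i = 1 − Σ_m (k_im/k_i)²*,
assortativity, and small-world σ = (C/C_null)/(L/L_null) against
degree-preserving rewired nulls — are evaluated at every density, and each
curve is summarised threshold-free by its trapezoidal area under the curve
(AUC).

Layer statistics: per measure, the per-layer AUC distributions across
participants are compared with a one-way ANOVA; global measures are
corrected across measures by Benjamini–Hochberg FDR (α = 0.05), nodal
measures across ROIs by Holm step-down (α = 0.01).  Each comparison carries
its *peak layer* (argmax of group-mean AUC).  Edge
consistency/variability (lowest/highest 5 % of per-edge standard deviations
across participants, tabulated per layer-pair block of the supra matrix),
cosine similarity between construction methods, significant-node counts
per region × hemisphere, and a cortical-thickness confound *t* test
complete the suite.

## Worked example

Run the full pipeline on a synthetic cohort with a planted superficial
density gradient (superficial layers ~twice as densely connected as deep
ones, with venous-drainage-like signal leakage):

```python
from laminarnet import PipelineConfig, run_pipeline
from laminarnet.synthetic import PLANTED_EFFECT

config = PipelineConfig(
    output_dir="demo_out",
    n_participants=10, n_roi=40, n_depths=3, n_timepoints=400,
    effect=PLANTED_EFFECT, share_structure=False, seed=7,
)
results = run_pipeline(config)
```

Selected output (seed 7):

```
pipeline          measure                      F       p_adjusted  peak_layer
layer_by_layer    avg_strength               42.51     1.59e-08    1
layer_by_layer    avg_clustering              7.24     4.74e-03    1
layer_by_layer    characteristic_path_length 47.90     6.14e-09    3
layer_by_layer    diameter                   58.88     9.99e-10    3
```

The planted gradient is recovered the way laminar physiology predicts it
should appear: strength and clustering AUC peak in the most superficial
layer 1 (denser superficial connectivity), while path length, diameter and
radius peak in the deepest layer (sparser deep layers are harder to
traverse).  Edge-consistency per-layer percentages for the same run were
`{1: 35.2, 2: 34.0, 3: 30.8}` — superficial layers carry the most
participant-consistent edges — and the layer-by-layer vs within-layer
method similarity AUC rose with depth (`0.286, 0.317, 0.367`), because
joint thresholding reallocates edges toward the leakage-inflated
superficial layers.

The same pipeline is available from a shell:

```bash
laminarnet synth --scale tiny --seed 1 --out fixtures/
laminarnet run-all --config fixtures/config.yaml
```

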