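# gradvar

Interindividual variability of functional-connectivity gradients: a toolkit
for embedding multi-subject cortical BOLD time series into a shared
low-dimensional *gradient space*, mapping where subjects disperse in that
space, relating the dispersion hotspots to intelligence measures with
cross-validated permutation inference, and profiling the hotspots' network
topology.

The package is aimed at researchers studying how individual differences in
resting-state functional organization relate to cognition. Because the
cohort data such studies use are typically access-restricted, `gradvar`
ships a first-class synthetic-cohort generator that plants known gradients,
dispersion hotspots, and brain–behavior couplings, so the entire analysis
chain can be exercised and validated against ground truth.

## The analysis

**Gradient embedding (generalized canonical correlation).** Each subject's
vertex × time matrix is z-scored per vertex within runs, the runs are
concatenated, and the r most informative principal components are
extracted per subject. The per-subject component matrices — weighted by
their singular values and normalized to unit total energy per subject — are
concatenated column-wise and decomposed with a second SVD. Its top-K left
singular vectors (K = 3 by default) are the group *functional gradients*
g₁…g_K; every subject is projected onto them within their own component
subspace, giving per-subject vertex coordinates in the common space. Two
explained-variance profiles are reported: the mean per-component fraction
of subject-level variance, and that fraction weighted by the cumulative
group-level explained-variance fraction.

**Dispersion mapping.** For every vertex v with subject coordinates
x_s(v) ∈ ℝᴷ, the group centroid is x̄(v) and the dispersion is

    D(v) = Σ_s ‖x_s(v) − x̄(v)‖²,

which decomposes additively across gradient axes. The total-dispersion map
is thresholded at the 95th percentile and suprathreshold vertices are
grouped into mesh-connected clusters, discarding clusters below 200 mm².

**Brain–behavior inference.** Crystallized (CI), fluid (FI), and general
(G) intelligence composites are built from ten task scores; G is the
loading-weighted mean Σ wᵢ zᵢ / Σ wᵢ with published factor loadings.
Behavioral and gradient measures are residualized on age, sex, handedness,
education, and mean framewise displacement. For each composite × gradient
axis, an OLS model on the clusters' coordinates is evaluated by 10-fold
stratified cross-validation with out-of-sample F and t statistics, tested
against permutation nulls (the subject-to-score assignment is permuted,
preserving the stratified fold structure), with Benjamini–Hochberg FDR
across models and post hoc t-tests. A cross-fold-averaged model is
additionally validated on a disjoint hold-out sample.

**Network topology.** Cluster-augmented parcellations yield parcel-averaged
time series; Pearson correlation graphs are thresholded to the 10%
strongest positive edges; six weighted node metrics (strength, global and
local efficiency, clustering, betweenness centrality, participation
coefficient) are computed per subject, z-profiled across nodes, and
correlated with the clusters' gradient coordinates across subjects.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from gradvar import build_mesh, CohortConfig, simulate_cohort, embed_cohort
from gradvar.dispersion import vertex_dispersion, extract_clusters, cluster_coordinates

mesh = build_mesh(20, 25, edge_length_mm=4.0)          # 500-vertex surface
config = CohortConfig(n_subjects=20, behavior_effect=-0.4, seed=1)
subjects, behavior, truth = simulate_cohort(mesh, config)

group, embeddings, _, profile = embed_cohort(subjects, k=3)
for j in range(3):
    rho = spearmanr(group.gradients[:, j], truth.gradient_maps[:, j])[0]
    print(f"gradient {j + 1}: |rho| vs planted map = {abs(rho):.3f}")

disp = vertex_dispersion(embeddings)
clusters = extract_clusters(disp, mesh, percentile=95, min_area_mm2=200)
print(f"{len(clusters)} dispersion cluster(s), "
      f"areas {[c.area_mm2 for c in clusters.clusters]} mm^2")

table = cluster_coordinates(embeddings, clusters)
r = np.corrcoef(behavior["fluid_latent"], table["c1_g1"])[0, 1]
print(f"fluid score vs cluster gradient-1 coordinate: r = {r:.2f}")
```

Output:

```
gradient 1: |rho| vs planted map = 0.974
gradient 2: |rho| vs planted map = 0.964
gradient 3: |rho| vs planted map = 0.993
1 dispersion cluster(s), areas [352.0] mm^2
fluid score vs cluster gradient-1 coordinate: r = -0.37
```

The three recovered group gradients track the planted spatial maps
(rank correlations ≥ 0.96); the planted high-dispersion patch survives
thresholding as a single 352 mm² cluster; and the fluid score correlates
with the cluster's principal-gradient coordinate near the planted
standardized slope of −0.4.

### Command line

```
gradvar simulate --subjects 120 --runs 4x150 --effect -0.4 --seed 7 --out cohort/
gradvar run --subjects 120 --folds 10 --perms 1000 --seed 7 --out run/
gradvar report --out run/
```

`gradvar run` executes simulate → embed → disperse → score → model →
graph → report, writes every intermediate as TSV/JSON, and records a
`manifest.json` with parameters, library versions, and per-file SHA-256
digests; two runs with the same seed are byte-identical.

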