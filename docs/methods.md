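# Methods notes

This document records the modelling assumptions, parameter choices, and
numerical conventions behind `gradvar`, including the places where the
design space was genuinely open and a choice had to be made.

## Gradient embedding

The embedding is a two-step generalization of PCA across subjects. Step 1
reduces each subject's normalized vertex × time matrix to its top-r
singular triplets. Step 2 concatenates the subjects' component matrices
column-wise and takes the top-K left singular vectors of the concatenation
as the group gradients.

*Normalization.* Each vertex's series is z-scored within each run (sample
SD, ddof = 1) and runs are concatenated. Constant series map to zeros
rather than being dropped, so vertex indexing stays aligned across
subjects.

*Per-subject rank r.* There is no canonical choice; the default keeps the
smallest number of components reaching 50% of the subject's total variance,
capped at 20, and is exposed as `rank=` / `--rank`. The rank is floored at
K so every subject can express all group gradients.

*Concatenation weighting.* Subject components enter the group SVD as
U·diag(σ)/‖σ‖₂ — singular-value-weighted, with each subject's total
(Frobenius) energy normalized to 1. Equal-energy normalization keeps any
one subject from dominating the consensus. Weighting columns by σ rather
than normalizing each column to unit norm is deliberate: with unit-norm
columns the concatenation's Gram matrix is a sum of subspace projectors,
whose leading eigenvalues are degenerate whenever subjects share the same
latent span — the individual gradient axes would then be an arbitrary
rotation of that span and irreproducible. Retaining the within-subject
variance ordering makes the axes identifiable.

*Signs and ordering.* SVD signs are fixed per gradient: against a template
map when one is supplied (the synthetic generator's planted maps serve this
role), otherwise by making the largest-magnitude element positive. Each
subject's projected coordinate columns are flipped to correlate positively
with the matching group gradient; zero-variance columns are flagged and
left at +1. Gradients are ordered purely by group singular value; no
reordering to match external gradient conventions is attempted.

*Projection.* Subject coordinates are the least-squares representation of
each group gradient within the subject's component subspace
(coords = S·S⁺·g). Component-domain projection was chosen over re-solving
in the time domain; with orthonormal scores the two coincide up to the
retained rank.

## Dispersion and clusters

The per-vertex centroid is the arithmetic mean of subject coordinates —
the minimizer of the sum-of-squared-distances statistic used for
dispersion. Dispersion is reported as the raw scatter (not divided by n);
`normalize=True` divides by (n − 1) for cross-cohort comparability.
Thresholding uses a linearly interpolated percentile and a strict `>`
comparison; connectivity is mesh edge adjacency with no geodesic dilation.
Clusters are labeled in order of descending area, ties broken by smallest
vertex index.

## Intelligence composites and confounds

CI and FI are unweighted means of their z-scored task subsets; G is the
loading-weighted mean over all ten z-scored tasks with published factor
loadings (weight sum 4.424). Z-scoring all composites from raw tasks keeps
the synthetic pipeline internally consistent even though operational
batteries often deliver pre-standardized CI/FI scores. Sex enters the
confound matrix as a 0/1 indicator and handedness as a signed continuous
score. Residualization is ordinary least squares on an intercept plus the
five confounds; estimation and hold-out samples are residualized
separately so no statistic leaks across the split.

## Cross-validated permutation inference

Folds are stratified by the dependent variable: subjects are ranked, cut
into k quantile bins (bins default to the fold count), shuffled within
bins, and dealt round-robin, so fold sizes differ by at most one globally
and within each stratum.

Per fold, an OLS model fit on the training folds is evaluated *out of
sample*: R² is computed on the test fold with test-fold centering,
F = (R²/p)/((1 − R²)/(n_test − p − 1)) floored at 0 for negative R², and
t_j = β_j/√(σ̂²·[(XᵀX)⁻¹]_jj) with σ̂² from the test-fold residual. A
numerically perfect fit (SS_res ≤ 1e−12·SS_tot) is reported as a +inf
sentinel and excluded from null pools with a warning. The across-fold
means of F and t are the test statistics.

The permutation null permutes the *subject-to-score assignment* (predictor
rows against fixed y), one shared permutation per iteration across all
folds, and averages the fold statistics exactly as for the real data. Two
alternatives were measured and rejected during development: independent
per-fold permutations under-correlate the null fold statistics across
folds, and permuting y against a fixed fold layout breaks the
y-stratification of the folds (real test folds then have systematically
wider y spread than null ones) — both inflate the type-I rate. With the
assignment permutation the real and null statistics are exchangeable under
the no-association hypothesis: the measured type-I rate at α = 0.05 is
0.060 over 200 null cohorts (n = 120, 6 predictors, 10 folds, 200
permutations), within the exact binomial 95% interval, and the p-value
distribution is consistent with uniform (KS p = 0.12).

p-values use the add-one rule, p = (1 + #{|null| ≥ |real|})/(1 + n_perm),
so p = 0 is impossible. FDR (Benjamini–Hochberg, via statsmodels) is
applied across the nine F-tests (3 measures × 3 axes) and across the
post hoc t-tests within each model.

Homolog cluster pairs declared by the user are averaged into a single
predictor when their across-subject Pearson correlation is ≥ `min_rho`
(default 0.6) on every axis; otherwise both columns are retained and the
decision logged.

Hold-out validation applies the across-fold-averaged coefficients to a
disjoint sample; its null permutes the hold-out dependent variable with
the averaged coefficients held fixed.

## Network topology

Graphs are weighted throughout (binarizing after a density threshold was
the main alternative; weighted metrics retain strength information and are
the stricter test of the implementation). Edge lengths for path-based
metrics are 1/weight; clustering is the geometric-mean (Onnela) triangle
coefficient with weights normalized by the maximum retained weight;
betweenness is unnormalized Brandes betweenness (networkx) on 1/weight
lengths; participation is 1 − Σ_m (k_im/k_i)² with weighted k and
communities fixed a priori from the parcellation. All variability clusters
share a single "cluster" community by default (`one_community_per_cluster`
switches to one community each). The density threshold keeps exactly
⌊density·n(n−1)/2⌋ strictly positive edges, ties broken lexicographically
by node pair; negative or zero correlations are never retained regardless
of density.

## Synthetic cohorts

The generator emulates the statistical skeleton of a multi-run
resting-state cohort, not its physiology: no hemodynamic model, folded
anatomy, or motion artifacts.

- Surface: a triangulated planar grid, default 20 × 25 vertices at 4 mm
  spacing (500 vertices, 7296 mm²), standing in for a cortical mesh at desk
  scale.
- Latent structure: K = 3 orthogonal smooth spatial maps with distinct
  spatial SDs (3.0, 2.0, 1.2) — the variance ordering both mimics the
  dominance of the principal gradient and makes the axes identifiable.
- Subject offsets: per-vertex Gaussian with SD 0.25 background and SD 1.0
  inside one contiguous 30-vertex planted patch (480 mm², comfortably
  above the 200 mm² cluster threshold), the ground-truth dispersion
  hotspot.
- Time series: four 150-timepoint runs by default; latent sources are
  low-pass-filtered Gaussian noise (σ = 3 timepoints), orthonormalized per
  run and scaled to unit per-timepoint variance, mirroring the slow
  dynamics that dominate resting fMRI; additive white noise SD 2.0 against
  per-vertex signal variance ≈ 14.
- Behavior: the fluid latent is β·z(cluster gradient-1 mean) + covariate
  terms + noise with the noise SD closing the variance to 1, so the
  planted β (default −0.4) is the expected Pearson correlation. Covariates
  draw age ≈ N(28.6, 3.6²), 0/1 sex, signed handedness, 11–17 years of
  education, and mean framewise displacement uniform on 0.04–0.24 mm.
  Task scores load 0.7 on their composite's latent and are emitted on a
  mean-100/SD-15 scale.

Passing tests on these cohorts demonstrates that each stage recovers the
structure it targets under clean, known-generative conditions; they say
nothing about preprocessing artifacts, spatial autocorrelation of real
BOLD noise, site effects, or behavioral measurement error, all of which
are absent from the generator.

The planted behavioral slope defaults to −0.4. Published effect sizes for
comparable vertex-level brain–behavior associations are far smaller
(standardized β around −0.16); −0.4 is a calibration choice that makes
recovery testable at cohort sizes of a few hundred rather than thousands.

## Problem sizes and determinism

Validation suites run at deliberately moderate sizes chosen as the
smallest that make the statistical claims meaningful: 10–20 cohorts of 20
subjects × 500 vertices for recovery checks, 200 null replicates for
calibration, 50 replicates for power, 200 permutations per model in
simulation studies (the pipeline defaults are 1000 CV and 10,000 hold-out
permutations), and 100 random graphs of up to 30 nodes against brute-force
oracles. All randomness flows from explicit seeds through numpy
`SeedSequence`; the pipeline writes per-file SHA-256 digests and two runs
with the same configuration are byte-identical.

## Known limitations

- The planar grid has a boundary (edge vertices have fewer neighbors and
  smaller areas), unlike a closed cortical sheet; area-threshold behavior
  near the boundary differs slightly from a real surface.
- The group embedding is computed on the full cohort before the
  estimation/hold-out split; computing it on the estimation sample only
  and projecting hold-out subjects post hoc would be stricter, at the cost
  of two embedding passes.
- Hold-out t nulls vary only through the permuted residual variance (the
  averaged coefficients are fixed), so their resolution is coarser than
  the CV t nulls.
- No anatomical labels are assigned to clusters; region names are user
  metadata.
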