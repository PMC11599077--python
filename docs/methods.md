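# Methods

This note documents the models and procedures implemented in `emsig`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not
demonstrate.

## Data model

A survey dataset is a respondents × items integer matrix of Likert
responses grouped into named scales (each with its own range, e.g. 1–5 for
three of the four vaccination-attitude scales and 1–4 for the fourth), an
ordinal dose outcome in 0–5 ("5 or more" is top-coded to 5), and
categorical demographics. Only complete, in-range rows are retained at
ingestion — incomplete responses are rejected and reported, never imputed,
matching the complete-case construction of this kind of cohort.
Reverse-phrased items are reflected onto the common direction by
v ↦ likert_min + likert_max − v; the operation is an involution and which
items are reversed is part of the user-supplied schema, since item phrasing
is instrument-specific.

## Factor extraction

Per scale, the item–item Pearson correlation matrix is converted to the
dissimilarity d(i, j) = 1 − pcc(i, j) ∈ [0, 2] (the standard transform for
clustering correlation structure; the method needs only a monotone
decreasing map) and clustered by Ward agglomeration. Cluster-count
selection over k = 2..8 uses two admissibility conditions and one
objective:

* **Centroid silhouette floor.** Items are embedded as the rows of the
  dissimilarity matrix, so cluster centroids are ordinary coordinate
  means; a′(i) is the distance from item i to its own centroid, b′(i) the
  smallest distance to another centroid, s′(i) = (b′ − a′)/max(a′, b′),
  and SC′ is the mean s′. Admissible k require SC′ ≥ 0.25 (the
  conventional boundary below which cluster structure is called weak). A
  classical-MDS embedding of d is an equivalent alternative; the row
  representation is used because it needs no additional decomposition.
* **Within-cluster PCC floor.** Every cluster's mean pairwise
  within-cluster correlation must reach a per-scale floor (0.7/0.6/0.5/0.6
  for the four shipped scale defaults; a flag switches the floor to the
  minimum pairwise value instead of the mean, since "a minimum PCC of at
  least x" can be read either way). Partitions containing singleton
  clusters are inadmissible: a one-item cluster offers no
  internal-correlation evidence, and admitting singletons would make
  k = n_items trivially optimal.
* **Objective.** Among admissible k, SC′ is maximized, ties to the smaller
  k. The pooled variance of within-cluster pairwise correlations is
  computed and reported per k as the cohesion–dispersion diagnostic but is
  deliberately not the objective: for nested Ward cuts it decreases
  monotonically in k (each further split removes the least-correlated
  pairs from the pool), so its argmin always sits at the top of the
  examined range rather than at the true structure, whereas SC′ peaks at
  the planted cluster count in every generator experiment (60/60 scale
  solutions over 15 seeds at within/between PCC 0.7/0.1).

Factor scores default to the cluster mean of a respondent's (reverse-
scored) item responses — mean rather than sum so that factors from 4-point
and 5-point scales live on comparable ranges and so that the score is
invariant to duplicating items; sum is available for a literal
"aggregating" reading. Factor identifiers follow the scale-prefix
convention (C-c1, D-c2, …) with an optional user label map: automatic
LLM-based annotation is intentionally out of scope, labels are an input.

## Latent projection and grid

Factor columns are z-scored (default on) and projected to 2D with UMAP
(15 neighbors, min_dist 0.1, Euclidean metric, fixed seed 42 — all
exposed; with a fixed random_state UMAP is single-threaded and bitwise
reproducible). PCA is provided behind the same interface: it is
closed-form, fast, and used throughout the test suite; any deterministic
n × 2 projector can be plugged in. The projection hyperparameters and the
standardization choice materially shape ROI geometry on real data and are
not canonical — they are configuration, not constants.

The grid spans the exact coordinate extrema with step 0.5 (nx =
⌈range/step⌉). Cells are half-open [edge, edge + step) with the last cell
per axis closed above, so cell membership is an exhaustive, disjoint
partition of respondents and the extreme point is covered.

## Spatial information gain

For one factor and one cell, members are split at the cell-local median of
the factor score (ties to the low group, deterministically). The cell SIG
is the expected KL divergence of the conditional dose distribution from
the prior over the split — with the default cell-local prior this equals
the plug-in mutual information I(dose; split) in nats (natural log matches
the KL form; conventions 0·log(0/q) = 0). Choices worth stating:

* **Conditioning variable.** The divergence formula needs a conditioning
  variable on the grid; the median binarization of one factor is the
  central interpretive choice here, giving one SIG map per factor whose
  expectation form is exactly plug-in MI, and letting per-factor maps be
  compared and summed.
* **Prior.** Cell-local dose distribution by default, so the posterior's
  support is contained in the prior's and the KL is always finite; a
  global-prior variant (divergence from the whole cohort's dose
  distribution) is a flag.
* **Occupancy floor.** Cells with fewer members than the floor (default
  5) get SIG 0. Plug-in MI is upward-biased by roughly
  (R−1)(C−1)/(2m) nats for m members, R split levels and C observed dose
  levels; because the aggregated surface sums 16 factor maps, this bias
  multiplies ~16-fold per cell while genuine signal usually lives in one
  factor, so sparse cells are pure noise amplifiers. Analyses of dense
  cohorts should raise the floor (the planted-ROI experiment uses 65; see
  below).
* **Aggregation** is an unweighted elementwise sum over factors (weights
  configurable), hence over scales.
* **Smoothing** uses the kernel h(p|v) = h_v·(1/√(2π)σ)·exp(−‖p−v‖²/2σ²)
  with σ = 1 in *embedding units* (at step 0.5 one σ spans two cells),
  summed over cell centers. The kernel is deliberately the printed 1-D
  normalization, not a normalized 2-D density, and the operation is linear
  in the raw surface. Note a consequence: a spatially diffuse field is
  amplified by the kernel sum (~2πσ²/step² · (2π)^{−1/2} ≈ 10× at the
  defaults) much more than an isolated peak (~1–3×), which is another
  reason biased sparse cells must be floored to zero.
* **ROIs.** The smoothed surface is thresholded at c = 34 % of its
  maximum (contour levels reported at 0/17/34/51 %); 8-connected
  components with at least 10 respondents become ROI subgroups, ordered by
  member count. An all-zero surface yields no ROIs, not an error.

## Subgroup profiling

Within each ROI, every factor's Pearson correlation with dose is computed
over members only and flagged at |r| ≥ 0.2 (the conventional lower bound
of a weak correlation); constant factors or constant dose make a factor
not-computable rather than unflagged. Demographic disparity uses a
one-sample chi-square goodness-of-fit test: null frequencies are the whole
cohort's category proportions (ROI members included) scaled to ROI size,
categories with expected count < 5 are pooled into an "other" bucket
(absorbing the smallest remaining expected counts until the bucket reaches
5 — expected-count adequacy being the validity condition of the chi-square
approximation), df = k − 1 post-pooling, significance at p < 0.05 with
star conventions */**/*** at 0.05/0.01/0.001. No multiple-testing
correction is applied by default, matching raw per-variable testing across
a dozen variables and a handful of ROIs; Benjamini–Hochberg is available
behind a flag. Under a cohort-null resampling experiment (ROIs of 100
drawn from a synthetic cohort of 5000) the realized type-I rate is
0.036–0.049 across variables — slightly conservative, as expected from
pooling, discreteness and the finite-population effect.

## Dose regression benchmark

Dose is treated as a numeric target in 0–5. The default suite covers
linear/generalized-linear models (OLS, ridge, lasso, LAR, lasso-LAR,
Huber, elastic net, OMP, passive-aggressive), a decision tree, k-NN,
Bayesian ridge, gradient boosting (sklearn GBM, LightGBM, XGBoost — the
latter two included when importable, skipped with a warning otherwise),
bagged ensembles (random forest, extra trees, AdaBoost) and a mean dummy
baseline, all at library defaults. Each model is fitted on a 70 % split;
the six metrics are computed on the held-out 30 %, with a 10-fold CV R² on
the training split reported alongside. Two metric conventions are forced
by the outcome and documented prominently because they affect
comparability with any published table:

* **RMSLE** clips predictions at 0 before log1p (log1p requires
  nonnegative arguments).
* **MAPE** is undefined at dose 0, which is a large share of a realistic
  cohort; it is computed over respondents with dose ≥ 1 by default, with a
  symmetric (sMAPE) variant behind a flag.

Predictor rankings come from (a) impurity-based feature importances of a
fitted tree ensemble and (b) Shapley values estimated in-package by Monte
Carlo permutation sampling (Štrumbelj–Kononenko): features are introduced
in random order on top of background rows drawn from the training data,
and a feature's attribution is its average marginal change in the
prediction — the interventional Shapley value, unbiased with variance
shrinking as 1/√permutations. The estimator satisfies efficiency
(attributions sum to f(x) − E[f]) and matches β_j(x_j − x̄_j) for linear
models and XGBoost's TreeSHAP rankings on test problems. Sensitivity
refits the model over 10 seeds of the 70/30 resampling and reports each
factor's frequency in the Shapley top 5.

## Synthetic-data generator

The generator is the package's testbed and defines its study conditions.

* **Item structure.** Each scale is a set of planted clusters; items load
  on a single cluster latent (item = λ·z_c + √(1−λ²)·ε) and are
  discretized at equiprobable standard-normal cutpoints into the scale's
  Likert range. Discretization attenuates correlations, so the configured
  within/between targets refer to the *post-discretization* PCC: the
  latent correlation is backed out through an exact lookup of the
  discretized-correlation curve computed from bivariate-normal rectangle
  probabilities (cached per Likert length). Realized within/between mean
  PCCs land within ±0.05 of the 0.7/0.1 targets at n = 5000.
  Between-cluster correlation within a scale comes from a shared scale
  factor; cross-scale latents are independent. Reverse items (a configured
  fraction per scale) are stored pre-reflected so reverse scoring recovers
  alignment.
* **Dose.** A standardized linear combination of cluster latents (default:
  three hesitancy-type factors), scaled, shifted, noised, rounded and
  clipped to 0–5. Alternative bases: the planted factor *scores* (used by
  the regression-sanity scenario, where the criterion is that a linear
  model recovers a dose that is linear in observable scores — with a
  latent basis, measurement attenuation caps the achievable R² near 0.84),
  or a constant (used by the ROI scenario's background).
* **Demographics.** Drawn per cohort category distributions (defaults
  follow the published cohort's frequency table), with per-subgroup
  distribution overrides — sufficient to exercise the chi-square stage
  without a causal model.
* **Planted subgroups.** A subgroup is a fraction of respondents whose
  latents are re-centered far from the origin (tight noise), giving them a
  coherent location in any reasonable embedding; one *driving* factor
  instead spreads around its own center and splits the subgroup's doses at
  its median (dose_low vs dose_high). The driver is the cluster *latent*
  by default — item measurement noise then decouples dose from embedded
  position at cell granularity, as in real data where attitudes are
  measured with error — or the observed score.

### The planted-ROI scenario

`roi_recovery_config` (n = 2000, subgroup fraction 0.2, background dose
constant, subgroup doses 0/5 split by the driving factor's observed score)
is engineered so that recovery is well-posed *under the method's own
estimator*, and its geometry encodes three lessons learned from the bias
analysis above:

1. the background dose is constant, so background cells carry exactly zero
   SIG rather than ~16 factors' worth of plug-in bias;
2. the analysis floor (65) sits above the densest background cell (~55
   members) while the subgroup's central cells hold 90–180 members, so
   even after dose permutation no background cell contributes;
3. two designated "spread" factors carry the subgroup's internal 2D
   geometry with more variance than the driving factor's score, so the
   embedding does not sort members by dose and the cell-median split
   aligns with the planted rule.

Under these conditions the top ROI matches the planted membership at
Jaccard ≥ 0.8 with the driving factor flagged by the |r| ≥ 0.2 screen in
~90 % of seeds, and globally permuting doses collapses the smoothed
maximum to well under half its planted value (median ratios ≈ 0.02–0.25).
The residual failures occur when a cohort-level principal axis happens to
align with the driving factor, so the embedding slices the subgroup into
dose-pure cells — an honest failure mode of median-binarized cell MI, not
of the test harness, and one that practitioners should expect whenever the
dose-driving construct dominates the embedding.

### What passing these experiments does and does not show

The generator's items are conditionally Gaussian single-factor blocks with
equiprobable discretization; real scale items have skewed margins,
cross-loadings, local dependence and missingness patterns that are not
emulated. Planted subgroups are spherical in latent space; real subgroups
are not. Demographic shifts are marginal-distribution overrides, not
confounded causal structure. Consequently the experiments validate the
*machinery* — calibration of the generator itself, exact oracle
equivalence of the estimators, recovery when the assumed structure is
present — and say nothing about whether a particular real cohort contains
such structure.

## Numerical and degenerate-input conventions

Zero-variance items abort the correlation matrix with the item named;
duplicate respondent ids and out-of-range responses abort ingestion (or
are dropped and reported, by configuration). Singleton silhouettes and
single-cluster partitions are errors, not NaNs. Degenerate median splits
(all members on one side) and constant-dose cells give SIG exactly 0. An
all-zero SIG surface yields an empty ROI list. A scale with no admissible
k is excluded from scoring with a manifest warning and the pipeline
continues; if every scale fails, the run fails. RMSLE/MAPE conventions are
above. All pipeline randomness flows from config seeds; reruns are
byte-identical.

## Known limitations

* The cell-median binarization ties SIG to the grid: a planted split that
  coincides with a cell boundary is invisible (see the ROI scenario
  notes). A soft or quantile-sweep conditioning would trade determinism
  for robustness.
* Plug-in MI bias makes aggregated SIG surfaces on sparse embeddings
  uninterpretable without an occupancy floor matched to local density; the
  default floor of 5 suits the published grid/step conventions, not every
  cohort size.
* The 34 % cutoff is relative to the surface maximum, so one dominant
  region suppresses weaker but genuine ROIs; when the dose signal is
  global rather than localized (as in the study-like default config) the
  threshold yields one large region — informative, but not a subgroup in
  the intended sense.
* Dose is modeled as numeric; an ordinal link would respect the outcome's
  scale but is out of scope.
* Selection of projection hyperparameters is unresolved in principle:
  ROI shapes on real data depend on them, and nothing in the method
  selects them automatically.
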