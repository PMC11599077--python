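# emsig

Subgroup discovery for vaccination-attitude surveys via embedding-based
spatial information gain.

## The problem

Cross-sectional vaccine-hesitancy surveys measure dozens of Likert items —
hesitancy toward the vaccine itself plus trust in doctors, pharmacists and
public health authorities — alongside a count outcome (how many COVID-19
vaccine doses the respondent has received, 0–5 with "5 or more" capped) and
demographics. Public-health teams want more than cohort-level regression
coefficients: they want *subgroups* of respondents who share similar
perceptions yet differ widely in uptake, because people whose attitudes
resemble those of vaccinated peers are the most promising targets for
tailored interventions, and they want to know *which specific concern*
separates the vaccinated from the unvaccinated inside each subgroup.

`emsig` implements that analysis end to end:

1. **Factor extraction** — reverse-score oppositely phrased items, build the
   item Pearson correlation matrix per scale, cluster items by Ward
   agglomeration on the dissimilarity d(i,j) = 1 − pcc(i,j), and choose the
   cluster count k ∈ {2,…,8} among candidates passing a centroid-silhouette
   floor (SC′ ≥ 0.25) and a within-cluster mean-PCC floor. Each item cluster
   is a *factor*; a respondent's factor score aggregates their responses
   over the cluster's items.
2. **Latent projection** — embed respondents' standardized factor-score
   profiles in 2D with UMAP (deterministic under a fixed seed; PCA available
   as a closed-form alternative), and lay a regular grid of step 0.5 over
   the coordinate extrema.
3. **Spatial information gain (SIG)** — for every grid cell and every
   factor, binarize the factor at the cell-local median and compute the
   expected Kullback–Leibler divergence of the conditional dose
   distribution from the cell's dose distribution,

   IG(X, A; X, a) = D_KL( P(x | a) ‖ P(X | I) ),   E_a[IG] = I(X; A),

   i.e. the plug-in mutual information (in nats) between the binarized
   factor and the dose among the cell's members. Per-factor maps are summed
   and interpolated with a Gaussian kernel
   h(p | v) = h_v · (1/√(2π)σ) · exp(−‖p − v‖²/2σ²), σ = 1.
4. **ROI subgroups** — threshold the smoothed surface at 34 % of its
   maximum (contour levels at 0/17/34/51 %), label 8-connected components,
   and collect each component's respondents as a region-of-interest (ROI)
   subgroup with dose mean ± SD.
5. **Profiling** — inside each ROI, flag factors with |Pearson r| ≥ 0.2
   against dose, and test each demographic variable's ROI counts against
   cohort-proportion expectations with a chi-square goodness-of-fit test
   (expected counts < 5 pooled; df = k − 1; p < 0.05).
6. **Dose regression benchmark** — a 17-model suite (linear/GLM, tree,
   k-NN, Bayesian ridge, gradient boosting, bagged ensembles, dummy mean
   baseline) on a 70/30 split with 10-fold CV on the training side,
   reporting R², MAE, MSE, RMSE, RMSLE and MAPE on the test set, plus
   feature-importance and Monte-Carlo Shapley rankings with a 10-seed
   top-5 stability profile.

Because respondent-level survey data of this kind are typically not
public, the package ships a first-class synthetic-data generator
(`emsig.simulate`) that plants known item-cluster structure, factor-driven
doses, demographic shifts and high-dose-variance subgroups, so every stage
is testable against ground truth.

## Worked example

```python
from emsig import (study_like_config, generate_dataset, reverse_score,
                   pcc_matrix, select_k, compute_factor_scores,
                   embed_pca, build_grid, compute_sig_surface, extract_rois)

dataset, truth = generate_dataset(study_like_config(seed=1))
dataset = reverse_score(dataset)
solutions = {
    s.scale_id: select_k(pcc_matrix(dataset, s.scale_id),
                         pcc_floor=0.55, scale_id=s.scale_id, prefix=s.prefix)
    for s in dataset.scales
}
print({sid: sol.chosen_k for sid, sol in solutions.items()})
# {'CoVaH': 4, 'T-DiG': 5, 'TRUST-Ph': 3, 'TiPHA': 4}

scores = compute_factor_scores(dataset, solutions)
print(scores.shape)
# (1020, 16)

emb = embed_pca(scores, seed=42)
surface, cells = compute_sig_surface(scores, dataset.dose, emb,
                                     build_grid(emb))
rois = extract_rois(surface.smoothed, surface.grid, cells, dataset.dose)
print([(r.roi_id, r.n, round(r.dose_mean, 2)) for r in rois])
# [('ROI-1', 881, 2.22)]
```

The chosen cluster counts recover the planted 4 + 5 + 3 + 4 structure
exactly (16 factors over 85 items), and the factor-score matrix feeds the
embedding and SIG stages. On this study-like configuration the dose signal
is global (three hesitancy factors drive everyone's dose), so the smoothed
SIG surface is diffuse and the 34 % cutoff yields one large region; the
planted-subgroup scenario (`roi_recovery_config`) instead produces a
localized ROI that matches the planted membership almost exactly.

Or from the shell:

```bash
emsig simulate --seed 1 --n 1020 --out survey.csv
emsig run-all --synthetic-seed 1 --outdir run1
emsig report run1/manifest.json
```

`run-all` writes per-scale quality tables, the partition, factor scores,
coordinates, SIG grids, the ROI table with memberships, per-ROI screen and
disparity tables, the regression report and a manifest; `report` renders
PCC heatmaps with cluster frames, the embedding scatter, the SIG contour
map and per-ROI pie-chart panels from the manifest alone.

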