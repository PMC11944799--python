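# Methods

This note documents the models, estimators, and numerical choices behind
`rarecycle`, and what the synthetic-data generator does and does not
emulate.

## Taxa partition

An OTU's class derives from its **mean relative abundance across all
samples**: abundant iff strictly above `abundant_min` (default 5·10⁻⁴),
rare iff strictly below `rare_max` (default 10⁻⁵), otherwise intermediate.
The mean-across-samples operationalization is the common convention in the
rare-biosphere literature; a per-sample variant is not offered because the
two disagree only for OTUs hovering at a threshold, and the mean is the
stabler statistic at n ≈ 41. Classification is invariant to per-sample
sequencing-depth rescaling because it uses relative abundances only.

The network pre-filter keeps the top `keep_fraction` (default 0.8) of OTU
*identities* ranked by mean relative abundance — i.e. 80% of the OTUs, not
80% of cumulative abundance — with lexicographic tie-breaking on OTU id so
the selection is deterministic.

## Diversity and statistics

- Shannon is computed in **nats** on relative abundances with 0·ln 0 := 0.
  Pielou evenness is `J = H/ln S` (0 when S ≤ 1), which makes the triple
  (richness, Shannon, Pielou) internally consistent.
- No rarefaction is applied before diversity: counts are converted to
  relative abundances as-is. Rarefaction changes richness estimates and is
  deliberately out of scope.
- Bray–Curtis runs on relative abundances (scipy `pdist`).
- **NMDS** is SMACOF majorization with monotone (isotonic) regression on
  dissimilarity ranks (scikit-learn `MDS(metric_mds=False)`), best of
  `n_starts = 20` seeded random initializations, k = 2 axes. The reported
  stress is Kruskal stress-1 of the returned configuration, recomputed
  directly from the definition (isotonic fit of configuration distances on
  dissimilarity ranks); the majorization loop inside scikit-learn is
  monotone by construction, so we assert the end-state quantity rather than
  per-iteration descent.
- **PERMANOVA** (scikit-bio): Anderson's squared-distance partitioning,
  single factor, free label permutation (no strata), p = (1 + #{F* ≥ F}) /
  (n_perm + 1); R² is derived from pseudo-F via
  R² = F(a−1) / (F(a−1) + (n−a)). **Mantel** (scikit-bio): correlation of
  lower-triangle entries with simultaneous row/column permutation of one
  matrix. Both are calibrated by simulation in the test suite (type-I error
  within [0.035, 0.065] at α = 0.05 over 1000 null datasets).
- **Kruskal–Wallis** is scipy's tie-corrected H with a χ² reference.
- **Duncan's multiple range test** is implemented here (no installed
  package provides it): one-way ANOVA MSE, harmonic-mean group size for
  unbalanced designs, and critical ranges from studentized-range quantiles
  at Duncan's protection levels `1 − (1−α)^(p−1)` for a span of p ordered
  means. Stepwise logic: a range is non-significant if its own test fails
  or it lies inside a larger non-significant range; letters come from the
  maximal non-significant ranges.
- **Correlation screens** report long-format (x, y, r, p). Pearson p-values
  use the t approximation. Spearman p-values are exact (full enumeration of
  the n! rank permutations) for n ≤ 8 and use the t approximation above
  that; the exact branch exists because the smallest crop group has n = 5,
  where the approximation is unreliable. Full enumeration beyond n = 8
  (0.36M+ permutations per pair) would dominate screen runtime for no
  practical gain.

## MNC index

`N_or = (X − X_min)/(X_max − X_min)` per variable with extrema taken over
**all provided samples jointly** (not per crop), and MNC is the row mean of
the seven normalized variables (SOC, TN, TP, TK, Olsen-P, Avail-K, NO₃⁻-N).
Constant variables are a hard error rather than being dropped: silently
changing n would redefine the index. MNC is invariant to positive affine
rescaling of any input (units cannot matter) and monotone in each variable.
Availability ratios (AN:TN, Olsen-P:TP, Avail-K:TK) are reported in
percent, converting mg kg⁻¹ numerators to g kg⁻¹ where needed.

## Co-occurrence networks

Edges are OTU pairs with Spearman |r| strictly above `r_min = 0.60` and
two-sided p strictly below `alpha = 0.05` across the crop's samples
(average-rank ties, t-approximation p). No multiple-testing correction is
applied by default — the thresholding convention this reproduces uses raw
p-values — but Benjamini–Hochberg is available (`p_adjust="BH"`).
Edge weight is |r| with the sign stored separately; isolated nodes are
dropped, so `node_num` counts connected nodes only.

Topology metrics (python-igraph backend, verified against from-definition
brute-force implementations on random graphs in the test suite):
average degree 2E/N; average weighted degree (mean nodal sum of |r|);
density 2E/(N(N−1)); diameter and average path length on the largest
connected component with unweighted shortest paths; mean local clustering
(degree < 2 contributes 0); global transitivity 3·triangles/triples;
degree assortativity (Pearson over edge endpoint degrees); Freeman degree
centralization Σ(d_max − d_i)/((N−1)(N−2)); average neighbor degree (mean
over nodes of the mean degree of neighbors — the Gephi-style
"average neighbors" reading, consistent with it exceeding average degree);
positive/negative edge fractions; Louvain modularity and community count
on |r| weights (resolution 1.0, seeded — python-igraph draws from Python's
`random` module, which is seeded and restored around each call).

**Robustness** is defined as the mean relative size of the largest
connected component after uniformly removing ⌊0.5·N⌋ nodes, averaged over
100 seeded draws. The quantity has no single canonical definition in the
literature; this random-removal convention is the dominant one for
microbial co-occurrence networks, and fraction/repetitions are
configurable. Published robustness values computed under an unstated
definition on other data are therefore not comparable; only the defined
identities (degree, density) are checked against printed values.

## Path model

The driver layer fits a **recursive path model on observed standardized
variables**: default diagram `salt → {rare, abundant} × {bacterial,
fungal} Shannon` and all four diversities plus salt → MNC. For a recursive
system with uncorrelated equation residuals, per-equation OLS on z-scores
gives the ML point estimates, so no iterative SEM optimizer is needed.
Fit statistics come from the implied covariance
`Σ = (I−B)⁻¹ Ψ (I−B)⁻ᵀ` (Ψ: exogenous covariances and residual
variances): `χ² = (n−1)(ln|Σ| − ln|S| + tr(SΣ⁻¹) − k)`,
`df = k(k+1)/2 − free parameters`, and
`RMSEA = sqrt(max(χ²−df, 0)/(df(n−1)))` (0 when df = 0; a saturated model
reproduces S exactly and is short-circuited to χ² = 0). Per-edge p-values
are t-based with `n − p − 1` degrees of freedom (one lost to centering).
The direct salt → MNC path is included by default — saturating the
ambiguous path avoids an unwarranted df claim — and can be dropped.

## Random-forest importance

A regression forest of 500 trees (scikit-learn `DecisionTreeRegressor`
base learners; features per split ⌈p/3⌉, the regression convention) with
explicit bootstrap resampling so that out-of-bag rows are known per tree.
Importance of a predictor is the mean over trees of the **percent increase
in that tree's out-of-bag MSE after permuting the predictor among the
out-of-bag rows** (%IncMSE). Model fit is the R² of the ensemble's
out-of-bag predictions. Exactly duplicated predictors split their
importance (neither captures more than ~90% of the pair's sum), the
documented collinearity behaviour of permutation importance.

## Synthetic generator

`generate_nutrients` draws each soil variable per crop from a normal with
the configured mean/SD (defaults transcribed from the emulated study's
physicochemical summary), truncated at zero by clipping. The truncation
bias is negligible for these means (< 0.1 SE at the tightest
mean-to-zero distance).

`generate_otu_table` draws a lognormal(0, σ²) abundance profile
(`sad_sigma` default 2.0 — the emulated data give no dispersion
information, so this is a documented free knob), applies per-sample
lognormal noise (`pert_sigma` 0.3, mean-corrected) and samples multinomial
counts at fixed depth 30 000. With the default 5000 bacterial / 800 fungal
OTUs the mean relative-abundance spectrum spans both classification tails.

`generate_coupled_dataset` plants the causal chain on the **pooled
standardized scale**, in generative order:

1. salinity per crop (truncated normal);
2. a latent rare-bacterial diversity target `t = 0.40·z_salt + √(1−0.40²)·ε`;
3. OTU tables whose *rare-tail mass* (OTUs below the rare threshold in the
   base profile) is tilted per sample by `exp(0.4·t)` — more tail mass
   means more detected rare OTUs and higher observed rare-community
   Shannon;
4. the *realized* standardized Shannon values of the rare/abundant
   sub-communities are computed from the sampled counts, and the seven MNC
   nutrients are shifted linearly in them:
   `z_M = −0.31·z_rb + 0.47·z_rf + √(1−0.31²−0.47²)·η`, with η a
   crop-structured residual (crop-level MNC means, orthogonalized against
   every regressor of the MNC equation) and each nutrient
   `X_j = ḡ_j + s_j(√(1−δ²)·z_M + δ·ε_j)` with per-nutrient noise δ = 0.4.

Because the nutrients respond to the realized (not latent) Shannon values,
the generative arrows coincide with the fitted ones and recovery is
well-posed: the −0.31/+0.47 edges are recovered essentially unbiased, and
the salt edge is attenuated only by the multinomial sampling noise in
observed rare Shannon (≈0.01–0.02 at default depth — the rare tail carries
a few hundred reads per sample, so the Shannon reliability is ≈0.95).
Design trade-off: in the coupled dataset, the seven MNC nutrients take
their crop structure *through the latent MNC target* rather than through
per-crop marginal means, so their crop means are muted relative to the
standalone `generate_nutrients`. Planting exact pooled-scale standardized
effects and exact per-crop nutrient marginals simultaneously is not
possible, and the effects are what the recovery tests quantify.

Not emulated: sequencing error, chimeras, compositional artifacts,
spatial autocorrelation, phylogenetic signal, and crop-level differences
in overall community composition (PERMANOVA R² on synthetic data is
therefore near its null level, unlike in real cropland surveys). Passing
tests demonstrate correctness of the estimators and pipeline plumbing
under these idealized conditions, not ecological realism.

## Problem sizes and determinism

Tests and the acceptance script run the pipeline at a desk scale chosen so
a full run completes in seconds: the full 41-sample study design with 1200
bacterial / 500 fungal OTUs (`default_run_config`); parameter-recovery
checks scale the design to ~500 samples at the full 5000/800-OTU default.
Null-calibration suites use 1000 simulated datasets with 199 permutations
each.

All randomness flows from one integer seed. The pipeline expands it into
per-stage seeds via `stage_seed = (seed·1000003 + stage_index) mod
(2³¹−1)`, so inserting a stage cannot silently shift earlier stages'
draws; numpy `default_rng` streams are used everywhere, scikit-bio and
scikit-learn receive explicit seeds, and igraph's Louvain is seeded
through Python's `random` module (state saved and restored). Identical
config and seed produce a byte-identical `report.json`.

## Known limitations

- Robustness (and any published value of it) depends on an arbitrary
  removal fraction and repetition count; comparisons across studies
  require matching conventions.
- The path model handles observed variables only — no latent constructs,
  modification indices, or bootstrap confidence intervals.
- Spearman p-values in network construction use the t approximation even
  at n = 5 (the smallest crop); the |r| > 0.60 threshold, not the p-value,
  is then the binding filter for most pairs.
- BIOM support is read-only and covers the standard 2.1 HDF5 layout
  (observation-major CSR with optional taxonomy metadata).
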