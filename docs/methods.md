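# Methods

`ipf` implements an integrative phenotyping pipeline for discovering
patient subtypes from several omics sources measured on one cohort —
typically a clinical ("phenome") table of mixed variable types plus one or
more expression matrices.  This note records the model, the numerical
choices, and what the synthetic benchmark does and does not demonstrate.

## Pipeline model

Let `X^(m)` be the features-by-samples matrix of source `m` (m = 1..M),
with features indexed by `I_m` and a shared sample index `J`.

1. **Pre-processing.**  Within each source, continuous features with low
   mean (below the `filter_mean_quantile` quantile of feature means) and
   then low standard deviation (below `filter_sd_quantile` of the remaining
   SDs) are removed; constant features are always removed; non-continuous
   clinical variables are exempt from the quantile stages.  Surviving
   non-categorical features are standardized to mean 0, SD 1 (sample SD,
   n−1 denominator — the convention is stated because results depend on it
   only through scale-free correlations, so either denominator gives the
   same downstream output; we fix n−1 for auditability).  Missing cells are
   preserved, never imputed.
2. **Feature fusion.**  Sources are concatenated feature-wise into `X`.  A
   type-aware correlation `R` is computed between every feature pair on
   pairwise-complete observations: Pearson for continuous–continuous (and
   binary pairs, where it reduces to the point-biserial and phi
   coefficients), Spearman whenever an ordinal variable is involved, and
   Cramér's V whenever a multi-class categorical variable is involved.
   The feature dissimilarity is `D = (1 − R) / 2`: identical features at 0,
   perfectly anti-correlated ones at 1, uncorrelated ones at ½.
3. **Embedding.**  Non-metric MDS (Kruskal stress over monotone transforms
   of `D`) places all features in 2D.  The optimisation is initialised from
   the deterministic classical-MDS configuration with fixed eigenvector
   signs, so a given seed reproduces coordinates bit-for-bit.  Axes are
   min-max rescaled to the unit square; the unscaled configuration is kept
   because the per-axis rescale is not an isometry.
4. **Smoothing.**  For each patient and source, the standardized feature
   intensities at the embedded coordinates are smoothed with a thin-plate
   regression spline and evaluated on the `(n+1)²` unit-square grid,
   producing the profile vector `c_j^(m)` (the numeric content of a feature
   topology plot).  Because correlated features co-locate, their redundant
   signal is down-weighted, and isolated noise features are averaged away.
5. **Clustering.**  Patients are compared by `1 − cor(c_j, c_j')` (Pearson
   on profile vectors) and clustered with PAM; the cluster count is chosen
   by a gap statistic.  Cluster-averaged profiles visualise each subtype.
6. **Integration.**  All source pairs are cross-tabulated through their
   cluster solutions with an optimal (maximum-weight bipartite) matching of
   cluster labels.  A pair whose off-diagonal fraction is at most
   `homogeneity_max_offdiag` (default 0.20) is *homogeneous*; the most
   homogeneous pair is merged — its features pooled and the patients
   re-smoothed and re-clustered on the *same* frozen embedding — and the
   comparison repeats until only heterogeneous pairs remain, which are
   reported side by side.  At most M − 1 merges can occur.
7. **Downstream.**  One-way ANOVA per molecular feature across the final
   clusters with Bonferroni control (default adjusted-p cutoff 1e-10)
   selects biomarkers; significant features are clustered into
   co-expression modules by PAM on `1 − cor` feature distance, after
   negating a caller-specified flip set (miRNAs, whose inhibitory action
   anti-correlates them with their mRNA targets); clinical variables are
   summarised per cluster with Kruskal–Wallis tests (pairwise tests
   unadjusted, as conventional in cohort description tables).

### Prediction on new cohorts

A fitted clustering is transferred to a held-out cohort by freezing the
embedding: features absent from the new cohort are dropped from both
cohorts, both are re-smoothed on the common feature set, and each new
patient joins the cluster of its nearest training medoid under `1 − cor`.
Nearest-medoid assignment (rather than refitting PAM) keeps the training
solution fixed, and guarantees that predicting the training cohort returns
the training labels exactly.  Validation re-clusters the new cohort
independently at the training K and reports the ARI between prediction and
re-clustering.

## Numerical choices

**Thin-plate smoother.**  Knot-based thin-plate regression spline: radial
basis `η(r) = r² log r` at up to 60 farthest-point knots (capped at half
the feature count), plus an unpenalised linear polynomial; radial
coefficients are constrained orthogonal to the polynomial and penalised by
the thin-plate energy.  The smoothing parameter is selected per patient by
GCV over a 15-point log-spaced grid (1e-6 … 1e4).  Consequences used by the
tests: constants and linear surfaces are reproduced exactly at any
penalty (they span the unpenalised null space), and the smoother is
shift-equivariant (GCV is invariant under adding a constant).  Patients
sharing a missingness pattern are fitted in one batched solve.

**Gap statistic.**  `W_k` is the pooled within-cluster sum of *squared*
dissimilarities, `Σ_r (1/2n_r) Σ d²` (the original definition of the
criterion).  The null reference matters with correlation distances on
smoothed profiles: axis-aligned uniform draws in profile space are
spatially rough and their dispersion barely depends on k, which lets the
gap drift upward indefinitely, and they also cannot reproduce the
near-planar surfaces GCV produces on pure noise.  The default null is
therefore drawn at the *feature* level — uniform over the ranges of the
PCA-rotated standardized feature matrix — and pushed through the same
thin-plate smoothing, so anything the pipeline manufactures on
structureless data is present under the null too.  K is chosen by the
largest upward jump of the gap curve (its "incremental difference"),
guarded by a one-standard-error comparison against k = 1 so an unclustered
cohort is reported as K = 1.  Tibshirani's one-SE rule, a global-SE rule
and plain argmax remain available (`gap_select(rule=...)`); the one-SE rule
stops at K = 1 whenever the gap dips at k = 2, which happens systematically
when three genuine clusters are forced into two.

**PAM.**  BUILD + best-improvement SWAP with ties broken toward the lowest
sample index, restarted from five deterministic anchors (the samples with
smallest total dissimilarity) and keeping the lowest-cost solution.
Single-start BUILD+SWAP reaches a local optimum on a few percent of small
ambiguous instances (the reference R implementation does the same on the
identical instances); the multi-anchor restart removes every such case we
measured at negligible cost.  The algorithm is deterministic; no seed is
consumed.

**Undefined correlations.**  Feature pairs with fewer than 3 complete
observations, or with a constant member, get correlation 0 (dissimilarity
½, the uninformative midpoint) with a warning, keeping `D` complete for
MDS.  Cramér's V is non-negative, so categorical pairs occupy only
[0, ½] of the dissimilarity scale — an unavoidable asymmetry for sign-free
association.  When a categorical variable is paired with a continuous one,
the continuous partner is quartile-binned before the contingency table.
Constant *profiles* get patient dissimilarity 1 (again neutral) with a
warning.

**Homogeneity threshold.**  0.20 on the off-diagonal fraction after
optimal matching; an agreement of ~88% of patients is comfortably
homogeneous and ~60%+ off-diagonal (independent partitions at K = 3) is
clearly heterogeneous, so the verdict is insensitive to the exact value in
between.  For K1 ≠ K2 the matching covers min(K1, K2) clusters and all
unmatched mass counts as off-diagonal.

## Synthetic data

The generator plants `k_true` latent patient clusters (balanced by
default; Dirichlet-skewed sizes optional).  Informative features receive
cluster means at equally spaced, centred levels separated by
`effect_size · within_sd`, with the cluster-to-level assignment randomised
per feature; noise features are `N(0, within_sd)`.  Binary, ordinal and
categorical variables are produced by thresholding a latent Gaussian at
balanced empirical quantiles (2, 4 and 3 levels respectively); categorical
level codes are shuffled so the variable carries sign-free association
only.  Missing cells are inserted uniformly at `missing_rate`, with every
row and column guaranteed one observed value.  The feature structure
(informative set, level assignments, types) is drawn from the spec seed
alone, while cluster memberships and noise are drawn per cohort, so
`simulate(spec, cohort=1)` yields a test cohort from the same population —
the discovery/validation setting.

Default study conditions used by the test suite and the acceptance script:
n = 90 patients, K = 3, 40 features per source, effect size 3 (clearly
separated subtypes) for cluster-count recovery and workflow behaviour;
effect size 1.5 with 100 features for the fused-vs-raw robustness
comparison, because at effect 3 both methods sit at the accuracy ceiling
(ARI 1.0) for low noise fractions and the comparison is uninformative;
noise fractions 0.3 / 0.6 / 0.9 span mostly-informative to
mostly-irrelevant feature sets.  Profiles use a 13×13 grid (n = 12) and
the gap statistic 10 reference draws — results were insensitive to finer
grids in our checks, and these sizes keep a full replicate under a second.

**What the benchmark does not show.**  Simulated features are Gaussian
with homogeneous within-cluster variance, independent noise and balanced
clusters; real cohorts have batch effects, heavy-tailed intensities,
correlated noise, informative missingness and unbalanced subtypes.
Passing tests demonstrate the machinery (correlation → embedding →
smoothing → clustering → integration) behaves as designed under its own
assumptions, not that subtype discovery will succeed on any particular
real data set.

## Known limitations

- The method needs enough features per source for the embedding and the
  smoother to be meaningful; very small assays (tens of features) degrade.
- Patient correlation uses all grid points, including regions of the unit
  square far from any feature, where the spline extrapolates; this adds
  variance to profile correlations but keeps profiles comparable across
  sources.
- The homogeneity decision is a threshold convention, not a test; in
  borderline cohorts the merge order can change the final grouping.
- Multi-class categorical variables contribute association magnitude but
  no sign, compressing their dissimilarity range.
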