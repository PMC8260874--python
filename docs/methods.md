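# Methods

This note documents the models, estimators, numerical choices, and known
limitations of the package, and what the synthetic-data generator does and
does not emulate.

## The data model

The unit of analysis is a proteins × samples matrix of log2 abundance from a
targeted panel (hundreds of proteins), with metadata per sample: species,
biofluid, subject, hours post injury, group (uninjured control/sham or a
severity grade), an ordinal severity grade, a continuous and a binary
recovery outcome, injury level, and processing plate (batch). Missingness is
treated as left-censoring at a lower limit of quantitation: a value is absent
because it fell below the assay's detection limit, not at random.

## Preprocessing

The chain is log2 → batch residualization → detection filter → half-minimum
imputation → within-species z-scoring, enforced by a forward-only
`scale_tag` on the matrix so stages cannot run out of order.

* **Batch residualization.** Per protein, least squares of the observed
  values on `[intercept | preserved design | centered batch indicators]`;
  only the batch component is subtracted, so preserved biological contrasts
  are untouched and the grand level is retained (centering). Missing entries
  are never invented here — imputation comes later, matching the convention
  that univariate fits handle batch as a model covariate instead.
* **Detection filter.** Proteins observed in at least one-third of samples
  are retained (inclusive comparison, applied per species/biofluid dataset).
* **Half-minimum imputation.** Missing values become half the protein's
  lowest measured linear-scale value, i.e. observed log2 minimum − 1. The
  scope is per protein (not the global matrix minimum): the detection limit
  is analyte-specific in targeted assays, and a per-protein floor keeps
  imputed values on each protein's own scale.
* **Cross-species z-scoring.** Ortholog-paired proteins are z-scored within
  each species' sample block, removing species-level location/scale so
  cross-species statistics see only relative patterns. Zero-variance
  proteins are dropped with a warning.

## Moderated differential abundance

Per protein g, OLS of log2 abundance on the outcome encoding plus
covariates over that protein's observed samples (complete-case per protein).
Encodings: binary (0/1), ordinal severity as equally-spaced numeric scores
(a single trend coefficient; ordinal grades like A/B/C have no measured
spacing, so the trend reading is the transparent default), continuous, and
categorical (indicator block tested by a moderated F). A `paired_subject`
column adds subject fixed effects for repeated-measures designs (pre/post
animal sampling); batch covariates are omitted there only when they would be
redundant with subject terms.

The empirical-Bayes prior (d0, s0²) is moment-matched on log residual
variances: with e_g = log s²_g − ψ(df_g/2) + log(df_g/2), the excess of
var(e) over mean ψ′(df_g/2) identifies d0 through the trigamma inverse
(Newton iteration, tolerance 1e-10), and the mean identifies s0². If the
excess is non-positive, or fewer than three proteins are available, the
prior degenerates to complete pooling (d0 = ∞) with s0² the mean variance.
The posterior variance is the convex combination
s̃²_g = (d0·s0² + df_g·s²_g)/(d0 + df_g); the moderated t uses df_g + d0
degrees of freedom, capped at the pooled total residual df (matching the
reference implementation's behaviour for very large d0). The test suite
checks agreement with limma's `lmFit`/`eBayes` to 1e-8 on a shared fixture.

Proteins whose observed design is rank deficient are flagged untestable and
excluded from the BH family rather than silently dropped.

Implementation note: proteins sharing an observation pattern share one
design decomposition, so complete (imputed) matrices fit in a single batched
solve — this is what makes 1000-permutation RRHO refits affordable.

## Sample networks and modularity

Samples are nodes; pairwise Pearson correlations are computed over the
proteins observed in both samples (pairwise-complete, no imputation, since
the correlation is defined on jointly quantified proteins). Networks are
built by rank: the strongest pairs enter until the edge count reaches
round(density · n(n−1)/2), with ties broken lexicographically by sample id
for determinism. Density targeting (rather than threshold sweeping) makes
curves comparable across datasets. Modularity is Newman's
Q = Σ_c (e_cc − a_c²) on the binary thresholded graph by default — the graph
is *defined* by thresholding, so the binary reading is primary — with a
`weighted=True` variant using the correlation weights, since the choice is
genuinely ambiguous. Pairs sharing fewer than 3 observed proteins can never
form an edge.

## Consensus clustering of trajectories

Input: per-protein log2 fold change versus uninjured controls at each
timepoint. For each k in range, 100 runs of k-means (Euclidean distance,
10 restarts each, best inertia kept) on random 80% protein subsamples;
consensus(i,j) = co-clustering count / co-sampling count. The per-k
assignment cuts an average-linkage dendrogram of 1 − consensus into k
groups; the direct k-means labels are discarded, following the referenced
consensus-clustering convention. Model selection uses the area A(k) under
the empirical CDF of off-diagonal consensus entries: k grows while the
relative gain (A(k) − A(k−1))/A(k−1) stays ≥ 10%. The 10% rule is the
conventional reading of "no appreciable increase"; smaller tolerances
over-select k, because even past the true k, subsample ambiguity adds a few
percent of area per extra cluster (configurable via `elbow_tol`). Clusters
with ≤ 2 members are pruned and survivors renumbered stably. Enrichment per
cluster is the upper-tail hypergeometric test of each flat gene set against
the clustered background with BH within cluster; no ontology graph is
consumed, so no conditional (parent–child) correction is attempted.

## Cross-species suite

* **π0/π1.** π0(λ) = #{p > λ}/(n(1−λ)) on λ = 0.05…0.95 (step 0.05),
  extrapolated to λ → 1 with a cubic-trend smoother (the high-penalty limit
  of a natural cubic smoothing spline; on a 19-point grid a cross-validated
  spline is needlessly wiggly), clipped to [0,1]. Degenerate p-value
  collections return the conservative π0 = 1 with a warning. π1 estimates,
  like all Storey-type estimators, carry sampling noise of order ±0.1 when
  only a few hundred p-values are tested; the validation suite therefore
  reports the median over replicate studies.
* **RRHO.** Each species' proteins are ranked by signed strength,
  −log10(p)·sign(β̂) (p floored at the smallest positive double; ties broken
  by |β̂| then id). For prefix lengths i, j on a stride grid (default
  ~100×100), the overlap o of the two top-lists is scored by the
  hypergeometric upper tail P(X ≥ o), and the grid holds −log10 p. The
  permutation test shuffles outcome labels within each species — at the
  subject level when the outcome is a subject attribute, within subjects for
  paired designs — refits both DE models, and compares the observed grid
  maximum (whole grid, the conservative default) with the permuted maxima
  using the add-one estimator (1 + #{max_b ≥ obs})/(1 + B).
* **NACC.** Within-species protein–protein Pearson correlation on the
  z-scored blocks; for protein g, the k = 10 most-correlated partners in
  species A are looked up in species B's correlation matrix and vice versa;
  the score averages the two directions (symmetric by construction, bounded
  in [−1, 1]). The null redraws k uniform random "neighbors" (excluding
  self) in both directions; z-scores and add-one permutation p-values are
  one-sided for conservation. Gene sets sized 3–50 within the scored
  universe are tested with the mean member score against size-matched random
  sets, reporting both conserved (≥) and divergent (≤) tails. Within one
  dataset, per-protein permutation p-values share the same correlation
  realization and are strongly dependent — uniformity of the null holds
  across independent realizations, not across proteins of one dataset.
* **Smoothing and DTW.** Per-protein time courses are smoothed by local
  quadratic regression with tricube weights (default bandwidth half the time
  range, widened locally until ≥ 3 points carry weight), evaluated on an
  upsampled grid strictly inside the endpoints. The alignment cost of
  (human time i, pig time j) is the Euclidean distance between the two
  all-protein vectors; the optimal monotone boundary-anchored path under
  steps {(1,0),(0,1),(1,1)} is found by dynamic programming with diagonal
  preference on ties. The recovered warp is the least-squares slope of human
  time on pig time along the path. Boundary anchoring assumes both series
  span the same biological interval; warp recovery is therefore assessed on
  grids with matched biological ranges (e.g. pig 12–60 h against human
  24–120 h under a 2× warp), and chronic far-out timepoints are excluded
  before alignment.

## The synthetic-study generator

The generator is the package's test bed and defines its study conditions.
Latent log2 abundance is baseline + injury effect × temporal profile
(evaluated at warp_factor × t for the pig, i.e. the pig response runs faster)
+ severity slope × grade + outcome slope × subject outcome + module factor +
batch offset + noise; values below the lod_quantile of the latent
distribution are censored.

Key choices, fixed a priori:

* **Cohort scale** mirrors a multi-hundred-sample two-species study: ~350
  proteins, human 3 grades × 12 subjects × 5 daily timepoints + 12 controls,
  pig sham + 3 grades × 10 subjects × 6 timepoints (12 h–12 weeks) with
  paired pre-injury baselines.
* **Effect fractions** follow the cohort proportions such a study reports:
  35% of proteins injury-responsive, ~20% of those severity-associated
  (slope sd 0.3 log2/grade), 10% outcome-associated; the recovery outcome
  correlates −0.6 with grade. These proportions make time, not severity, the
  dominant variance axis — the study signature the modularity stage must
  reproduce.
* **Temporal profiles** form a small parametric library (hyper-acute spike
  τ = 12 h, early spike τ = 24 h, delayed logistic rise, monotone decline,
  fast sustained), all zero at t = 0. The hyper-acute class is what makes
  the earliest timepoint's DE set a Jaccard outlier.
* **Planted effect sizes** have random sign and magnitude uniform on
  [0.5, 2] × effect_size_sd. A mean-zero draw would plant "positives" of
  arbitrarily small size and make sensitivity against the truth ledger
  ill-defined; every planted association is a genuine signal by
  construction.
* **Modules.** One latent N(0,1) factor per module per sample; members load
  ±√ρ on it (within-module correlation ρ, default 0.6). Conserved modules
  keep membership and loadings in both species; divergent modules re-draw
  their pig membership from module-free proteins, so the reference members
  carry no pig coexpression structure — a sign-only re-draw leaves pig
  members mutually correlated and makes divergence detection ride on
  binomial sign-alignment noise.
* **Missingness** is pure left-censoring (no MCAR component), matching
  targeted-MS detection limits. Sample dropout, when enabled, is uniform at
  a configurable rate — real attrition mechanisms (catheter loss, death) are
  not modeled.
* **Determinism.** All randomness flows from one integer seed through
  `numpy.random.default_rng`; identical config + seed gives bit-identical
  matrices, metadata, and truth ledger.

What passing tests on generated data do **not** show: robustness to
peptide-level rollup artifacts, non-Gaussian heavy-tailed noise, informative
dropout, nonlinear warps, ortholog mis-mapping, or assay-specific QC
failures — none of which the generator emulates.

## Validation problem sizes

The validation suite (tests and `scripts/acceptance.py`) runs oracle checks
on exhaustive small instances (graphs ≤ 16 edges, rank lists of 9, DTW grids
≤ 6×6), calibration on 200–300-protein null studies over 20–50 replicates,
π1 recovery at 1000 proteins (median of 5 replicate studies), warp recovery
at 250 proteins on dense matched grids, NACC power at 200 proteins with
size-25 modules (ρ = 0.8, B = 200), and the end-to-end smoke run at 150
proteins with B = 99 permutations. These sizes were chosen to keep the whole
suite within a few minutes while leaving each estimate's Monte-Carlo error
well inside the asserted tolerance bands.

## Known limitations

* Per-timepoint models only; no joint longitudinal (mixed-effects or spline)
  model across timepoints — the categorical-time moderated F is the pooled
  alternative offered.
* The π0 smoother is a fixed cubic trend, not a tunable spline.
* DTW has no slope constraint or windowing; pathological cost matrices can
  produce degenerate staircase paths.
* NACC assumes the two panels are large and diverse enough for "random
  neighbors" to be an exchangeable null; tiny universes (tens of proteins)
  make the null grid coarse.
* The generator's warp is linear; the DTW stage can represent nonlinear
  warps but is never tested against them here.
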