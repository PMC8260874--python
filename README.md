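# conservatome

Statistical machinery for **two-species time-course biofluid proteomics**:
given protein-abundance panels measured serially in an injured human cohort
and in a parallel large-animal model (e.g. CSF or serum after spinal cord
injury), quantify what changes, when, and how well the two species' responses
agree. The package is aimed at computational biologists analyzing targeted
(MRM/PRM-style) protein panels with graded injury severity, longitudinal
sampling, plate batches, and detection-limit censoring.

## What it computes

**Preprocessing** — log2 matrices with explicit missingness; batch
residualization (per-protein least squares on `[design | batch]`, batch
component subtracted); detection filtering (proteins observed in ≥ 1/3 of
samples); half-minimum imputation (missing → observed log2 minimum − 1);
within-species z-normalization for cross-species work.

**Moderated differential abundance** — per protein *g*, OLS on the outcome
(injury status, ordinal severity grade, or continuous recovery, with
covariates and optional subject fixed effects for paired designs), then
empirical-Bayes shrinkage of residual variances: the prior (d₀, s₀²) is
moment-matched on log s²_g, the posterior variance is

```
s̃²_g = (d0·s0² + df_g·s²_g) / (d0 + df_g)
```

and t_g = β̂_g /(s̃_g·u_g) is referred to t(df_g + d₀), with
Benjamini–Hochberg FDR control. Verified against limma's `eBayes` to 1e-8.

**Sample-network modularity** — threshold the sample–sample Pearson
correlation matrix to a target edge density and compute Newman's
Q = Σ_c (e_cc − a_c²) for a given grouping (timepoint, severity, subject, …)
as a function of density: the grouping with the higher curve drives proteome
variation.

**Consensus trajectory clustering** — k-means over protein log2-fold-change
trajectories with 100 protein subsamples per k; co-clustering fractions form
a consensus matrix, k is selected where the relative gain in consensus-CDF
area falls below 10%, clusters of ≤ 2 proteins are pruned, and clusters are
annotated by upper-tail hypergeometric gene-set enrichment (GMT input).

**Cross-species conservation suite**
- **π1 = 1 − π0** (Storey): fraction of human-significant proteins with a
  real effect in the second species, no threshold needed in that species.
- **RRHO**: both species' proteins ranked by signed −log10 p; the
  hypergeometric enrichment of every pair of top-list prefixes forms a
  significance grid whose maximum is calibrated by label-permutation refits.
- **NACC**: each protein's k = 10 nearest coexpression neighbors in one
  species are looked up in the other; the symmetrized mean neighbor
  correlation is compared with random neighbor sets (protein-level and
  gene-set-level permutation tests, conserved and divergent tails).
- **DTW**: dynamic time warping of the smoothed whole-proteome time courses
  recovers the temporal offset between species (local cost = Euclidean
  distance between all-protein abundance vectors per timepoint pair).

**Synthetic-study generator** — first-class, tested code that emulates the
full design (two species, graded severity, timepoints, batches, conserved
/divergent coexpression modules, left-censoring, a known linear time warp)
and emits a ground-truth ledger, so every stage above can be validated by
parameter recovery.

## Worked example

`examples/` holds one short script per capability. For instance:

```bash
$ python examples/03_sample_network_modularity.py
density   Q(time)   Q(severity)
  0.05     0.124      0.099
  0.10     0.104      0.068
  0.20     0.086      0.064
  0.30     0.077      0.053
  0.50     0.062      0.041
```

Q(time) exceeds Q(severity) at every density: in this simulated cohort —
as in real acute-injury biofluids — time post injury, not injury severity,
is the dominant driver of proteome variation.

```bash
$ python examples/05_cross_species_conservation.py
shared (ortholog-mapped) proteins analyzed: 197
NACC: 84 of 197 proteins with significantly conserved coexpression (perm p<0.05)
gene sets: 5 conserved, 4 divergent at perm p<0.05
pi1 (shared response fraction) per matched timepoint:
 timepoint_h  n   pi1
        24.0 50 0.798
        48.0 44 0.000
DTW warp slope (human hours per pig hour): 2.00
```

The warp slope of 2.00 recovers the planted 2× speed-up of the pig response;
π1 ≈ 0.8 at the earliest matched timepoint but collapses later, because under
a 2× warp equal clock times are biologically mismatched — the misalignment
the DTW step quantifies.

A thin CLI wraps the same library calls:

```bash
conservatome simulate --out study/ --seed 7
conservatome de --matrix study/human_abundance.tsv --meta study/metadata.tsv \
    --outcome severity_grade --encoding ordinal_numeric --covariates batch \
    --timepoint 24 --out de24.tsv
conservatome run --config cfg.json          # both workflows end to end
```

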