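# Methods

## Statistical model and procedure

The pipeline compares two sample groups (mutant, MUT; wild type, WT) within
each of two expression cohorts, then replicates findings across cohorts.
All tests are two-sided.

**Differential expression.** Each gene is tested with the Wilcoxon rank-sum
test. The default p-value is the normal approximation on mid-ranks with
tie-corrected variance and continuity correction — standard at cohort
sample sizes (both emulated designs have ≥ 90 samples overall). An exact
mode enumerates all C(n1+n2, n1) group labelings for n1+n2 ≤ 12 and
reports twice the smaller one-sided tail (capped at 1), the same two-sided
convention R's `wilcox.test` and scipy's exact method use; it exists as the
small-sample oracle for the approximation and as an option for tiny
pilots. The rank-sum test assumes exchangeability under the null and
nothing about the expression scale: its p-values are invariant under any
strictly monotone transform, which is what justifies mixing RSEM-style
counts and log-scale microarray intensities in one protocol. Direction of
change (UP/DOWN in MUT relative to WT) is taken from the group means; exact
ties give NONE and are excluded from direction-matched replication.

**Differential co-expression.** For a gene pair, the per-group Pearson
correlations r_wt and r_mut are Fisher-transformed, z = atanh(r), and the
difference is referred to the standard normal with the classical standard
error sqrt(1/(N_wt−3) + 1/(N_mut−3)). This test assumes approximate
bivariate normality within groups and N > 3 per group (the variance term is
undefined otherwise; smaller groups are a hard error). Before pairing,
genes are ranked by expression variance pooled over all samples (unbiased
n−1 denominator) and the top ceil(fraction·n) are kept — the pooled
variance deliberately includes the between-group component, so strongly
shifted genes enter the panel even when their within-group spread is
modest. The multiple-testing family is all C(m, 2) pairs of the m-gene
panel, including any pairs later dropped because a gene had zero variance
within one group.

Two replication rules are provided. The strict rule intersects the
significant pair lists of the two cohorts on canonical (lexicographically
ordered) gene-symbol keys. The relaxed rule keeps pairs whose correlation
change has the same sign in both cohorts and that are corrected-significant
in one cohort while at least nominally significant (raw p < 0.05) in the
other — the asymmetric criterion appropriate when one cohort is much
smaller.

**Integration and downstream profiling.** The integrated gene set is the
intersection of the replicated (same-direction) DEGs with the genes present
in both cohorts' significant DCE results. These genes are clustered on the
induced subgraph of a user-supplied weighted interaction network using
Markov clustering, and profiled by one-sided hypergeometric
over-representation against GMT collections with BH FDR applied per
collection (each collection is its own test family, since sources differ
in size and redundancy). The enrichment background defaults to the union
of the collection's genes and the genes actually tested in the calling
stage (the variance-filtered panel); callers can override it. Enrichment is
upper-tail only: the workflow asks about over-representation, never
depletion.

**Classification.** L1-penalised logistic regression with stratified
k-fold cross-validation is fit on one cohort's standardised candidate
genes over a logarithmic penalty grid; the penalty minimising mean
cross-validated log-loss is kept ("minimal lambda" rule) and the nonzero
coefficients define the predictor panel. Evaluation on the other platform
has two protocols. The default `refit` protocol refits a plain logistic
model on the *target* cohort restricted to the mapped genes and reports its
in-sample AUC: it measures whether the selected panel separates the target
groups at all, and is the protocol behind near-perfect published AUCs of
this design. The stricter `transfer` protocol freezes the source-fitted
model and scores the target samples, with each platform standardised
independently. AUC is computed in its Mann–Whitney form,
P(score_MUT > score_WT) + ½·P(equal).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | significance level for every corrected test family |
| `fraction` | 0.25 | variance-filter quantile for the DCE panel |
| correction, cohort A | bonferroni | family-wise control on the larger cohort |
| correction, cohort B | bh | explicit relaxation for the smaller cohort, stated in the config, never silent |
| `nominal_alpha` | 0.05 | raw-p bar in the relaxed pair-replication rule |
| MCL `inflation` | 2.0 | granularity of Markov clustering (canonical default) |
| MCL `expansion`, `prune`, `tol` | 2, 1e−5, 1e−6 | flow power, sparsity floor, convergence bar |
| `top_k` | 150 | genes per direction in GRP signature export |
| `n_folds` | 10 | stratified CV folds for penalty selection |

## The synthetic data generator

`synthetic_data` emulates the two-cohort design the pipeline targets: a
large cohort with a 93/415 WT/MUT split and a small one with 14/166 —
the group proportions of the public lower-grade-glioma cohorts this
workflow is designed around — at a desk-scale 2,000 genes. Differential
expression is planted as a mean shift in the MUT group, default 2 SD in
units of the noise SD (25 genes up, 25 down). Differential co-expression is
planted as exchangeable correlation blocks: each block of k genes is drawn,
per group, from a multivariate normal whose correlation matrix has a single
off-diagonal value (default 20 blocks of 2 genes, r_wt = 0.9 → r_mut = 0.0,
a complete loss of co-expression in the mutant group). Exchangeable blocks
are the minimal structure reproducing pairwise correlation targets; the
positive-definiteness constraint r > −1/(k−1) is enforced with an explicit
error. A configurable fraction of the planted signals (default 0.5) is
shared between platforms with identical directions and correlation values;
platform-private signals are relocated to otherwise unused gene indices so
the private truths are disjoint. The default block genes are a subset of
the DE genes, for two reasons: the between-group shift lifts their pooled
variance into the top-25% panel (a pure correlation change leaves marginal
variances untouched and would be removed by the filter), and the DEG∩DCE
integration stage then has a non-empty planted truth.

Draws are a pure function of (seed, config, platform_id): each platform
gets its own stream keyed by a hash of its identifier, so adding a platform
never perturbs another's data. A lognormal marginal (exponentiating the
Gaussian field) is available to mimic right-skewed count-like scales.

What the generator does **not** emulate: library-size or batch effects,
platform-specific probe noise, count discreteness, heavy-tailed outliers,
correlated background structure beyond the planted blocks, and
probe-to-gene multiplicity (probe collapsing is exercised with its own
fixtures instead). Passing recovery tests therefore demonstrates that the
statistics detect what they are defined to detect at realistic sample
sizes — not that real cohorts are free of the confounders above, which
must be handled upstream (the pipeline deliberately performs no
normalisation of its own).

## Numerical choices

- The Fisher transformation is implemented as z = ½ ln((1+r)/(1−r)) and the
  difference statistic carries the square root over the summed variance
  terms — the classical forms, which reproduce the magnitude of published
  p-values for this design (e.g. r 0.93 → 0.75 at a 93/415 split gives
  Z ≈ 5.9, p ≈ 4e−9 from the rounded correlations).
- Correlations within 1e−7 of ±1 are clamped before atanh so degenerate
  (numerically perfect) correlations give a large finite z, not ±inf.
- DCE tail p-values go through the normal log-survival function and remain
  accurate far below 1e−300; beyond float64 range they underflow to 0.
- The hypergeometric upper tail is an exact log-space sum (gammaln +
  logsumexp); it matches Fisher's exact one-sided p to 1e−10.
- BH accepts an external family size m ≥ len(p), matching R's
  `p.adjust(..., n = m)`, so a subset of a larger family is corrected
  against the full family.
- Variance-filter ties at the cutoff break by gene symbol ascending; pair
  keys are canonical lexicographic order; GRP ranking ties break by symbol.
  Every ordering in the package is total, which is what makes reruns
  byte-identical.
- MCL adds self-loops at each node's maximum incident weight (1 for
  isolated nodes), column-normalises, and iterates expansion/inflation with
  pruning below 1e−5 until the matrix moves less than 1e−6 or 100
  iterations (non-convergence returns the current interpretation with a
  flag). Clusters are read from attractor rows; overlapping attractor
  systems are merged, resolving MCL's overlapping-cluster ambiguity
  deterministically. Nodes are processed in sorted order, so output is
  invariant under input permutation.
- Probe collapsing keeps the probe with the highest variance across all
  samples for each gene — a standard convention that also interacts
  correctly with the downstream variance filter.
- The target-side logistic refit uses an effectively unpenalised fit with a
  weak L2 term (C = 1e6) as a separation guard: with perfectly separating
  panels the coefficients stay finite and the scores stay usable.

## Statistical subtleties worth knowing

- The label-permutation null of the correlation-difference statistic is
  conditional on the realized sample; its dispersion varies from dataset to
  dataset, so the analytic standard-normal p agrees with the permutation p
  in aggregate (zero mean difference across datasets, and matching
  unconditional rejection rates) but not pointwise on any single dataset.
  The test suite checks exactly the aggregate statement.
- BH controls the *expected* false-discovery proportion. With ~50
  discoveries a single run's realized FDP is granular (steps of ~1/50) and
  exceeds the nominal level in a substantial fraction of replicates even
  for a perfect implementation; recovery checks therefore assert the
  replicate-mean FDP.
- The normal approximation to the rank-sum test is compared against exact
  enumeration on continuous data; with heavy ties at very small n
  (n1+n2 ≤ 12) the approximation can drift by several hundredths and the
  exact mode should be used instead.

## Problem sizes used by tests and the acceptance script

Simulated checks run at the emulated cohort splits (93/415 and 14/166)
with 2,000 genes for expression-level recovery, 46–200 genes for pairwise
power checks (≥ 1,000 pairs per family), 20 replicates of ~2,000 pairs for
null calibration, and 10^5 shuffles for permutation oracles — sizes chosen
so every planted effect is tested at full strength while the whole suite
runs in minutes on one core.

## Known limitations

- No covariate adjustment, model-based DE (DESeq2/edgeR/limma class), or
  survival analysis; the DE statistic is deliberately rank-based.
- Spearman or partial-correlation variants of the DCE test are not
  implemented; WGCNA-style module detection is out of scope by design
  (module membership is a different question from pairwise correlation
  change).
- Enrichment uses plain BH per collection rather than multi-database
  corrections of hosted services, and ships no annotation databases:
  collections are user-supplied GMT files.
- The cluster count produced by MCL depends on inflation and on the
  supplied network; it is a description of the induced subgraph, not a
  reproduction of any externally hosted clustering.
- The `refit` evaluation protocol reports an in-sample AUC on the target
  cohort by design; use `transfer` for an honest out-of-sample transfer
  estimate.
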