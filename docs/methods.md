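# Methods

`cllnet` re-implements, as a tested pipeline, the master-regulator
inference chain used to study prognosis in chronic lymphocytic leukemia
(CLL): a multi-cohort differential-expression (DE) meta-analysis between
IGVH mutational statuses, mutual-information (MI) regulatory network
reconstruction, regulon enrichment against the DE signature, and
survival-based evaluation of the candidate regulators.  Because the
original analysis rests on microarray cohorts that this package does not
ship or download, a synthetic-data generator with planted ground truth
stands in for them; every stage is validated by recovery of that truth.

## The synthetic model

**Expression.**  Gene expression is linear-Gaussian on a log-like scale.
Each transcription factor (TF) is drawn independently per sample; each of
its targets equals `coupling x TF + noise` with Gaussian noise of standard
deviation `noise_sd` (default 1.0).  A target owned by several TFs sums
their contributions.  A TF's marginal variance is
`noise_sd^2 + coupling^2` — intrinsic noise plus a unit-variance
regulatory drive — so regulators are as variable as the targets they
drive, the model degenerates to pure noise at coupling 0, and targets
become deterministic functions of their TFs as `noise_sd -> 0`.  The
linear-Gaussian choice is deliberate: the Gaussian case has the closed
form `MI = -0.5 ln(1 - rho^2)`, which gives the kernel estimator an exact
oracle.

**Regulons.**  `generate_truth` plants `n_tfs` regulons of
`targets_per_tf` targets.  A fraction `overlap_fraction` of each regulon
is drawn from a shared pool of `targets_per_tf` genes (so regulons overlap,
as the top CLL regulators' target sets do); the rest are exclusive, which
keeps every planted regulator identifiable.  The first `min(3, n_tfs)` TFs
are the *masters*: the DE gene set is their pooled targets, topped up with
independent genes to reach `n_de`.

**Two-group contrast.**  DE genes receive `+group_shift` ("Up") or
`-group_shift` ("Down") in the unmutated-IGVH group.  Poor prognosis is
anchored to the unmutated group throughout, matching the clinical
convention that unmutated IGVH carries the less favorable prognosis.
Defaults (`group_shift = 1.5`, `noise_sd = 1`, cohorts of 60 + 60) give a
per-study noncentrality around 8 for an unregulated DE gene, i.e. strong
but not trivial per-study evidence — the meta-analysis still improves on
any single study.

**Gene properties.**  Per-gene baseline intensities and variability are
deterministic functions of the truth seed (a gene's identity is a property
of the universe, not of one cohort).  Genes involved in the planted
regulation are "expressed" (baseline ~ N(9.5, 0.5)); background genes
spread lower (~ N(7, 1.5)), emulating the non-expressed fraction that a
mean-intensity filter removes.  With `sd_jitter > 0` (demo default 0.3),
background noise SDs are log-normally heterogeneous, giving the
continuous, unimodal SD distribution that the shorth-based filter assumes;
planted genes keep `noise_sd` exactly so the calibration properties of the
generator are untouched.

**Survival.**  Outcomes follow an exponential proportional-hazards model:
event time ~ Exp(rate `baseline_rate * exp(lp)`) with linear predictor
`lp = sum(coefficient x standardized expression)` over the planted
survival genes (a subset of the DE genes, log-HR +/-0.7 per SD, sign
matching the DE direction: "Up in poor prognosis" raises hazard).
Censoring is independent exponential; time-to-treatment uses a 3x larger
baseline rate than overall survival (treatment precedes death).  The
exponential/exponential choice keeps every hazard closed-form.

**What the generator does not emulate:** probe-level artifacts, batch and
platform effects, non-Gaussian marginals, feedback loops, and
TF-TF regulation.  Passing recovery tests therefore demonstrates
correctness of the chain under its own model assumptions, not performance
on real microarray data.

## Preprocessing

Two paths, as in the original workflow:

* **DE path** — per-cohort two-step filter (drop the lowest 30% of genes
  by mean, then the lowest 30% of the remainder by variance; the
  fractions are applied sequentially, mirroring the two-step filter of the
  standard meta-analysis toolkits), optional IQR probe summarization (per
  gene, keep the probe with the largest interquartile range; ties broken
  by the smallest probe id so the result is independent of row order),
  then a merge retaining genes present in >= 80% of cohorts.  Cells for
  absent (gene, cohort) pairs are missing and are excluded per-study
  downstream, never imputed.
* **Network path** — per-cohort shorth SD filter: a gene is kept when its
  SD is at least the shorth (mean of the shortest contiguous half-sample)
  of the cohort's SD distribution.  Equal-width windows resolve to the
  leftmost; a tiny relative slack (1e-12) keeps exact SD ties.

## Meta-analysis

Each study contributes a pooled-variance two-sample t-test per gene (the
classical input of microarray meta-analysis); direction is the sign of the
unmutated-minus-mutated mean difference.  Per-gene p-values are combined
over the `K_g` studies that observed the gene:

* Fisher: `S = -2 sum ln p_k` against chi-square with `2 K_g` df;
* Stouffer: `sum Phi^-1(1 - p_k) / sqrt(K_g)` against the standard normal;
* maxP: `(max p_k)^{K_g}` (order-statistic tail);
* rOP: Beta(r, K_g - r + 1) tail of the r-th smallest p, with r clipped
  per gene to `K_g` (the 80%-presence merge makes K vary by gene);
* AW (experimental): exhaustive binary study-weight search, best-subset
  Fisher statistic referenced against a 1000-permutation null per
  missingness pattern.

Benjamini-Hochberg FDR is applied across genes within the chosen method
only.  The signature is the list of genes with q below 0.05, directions
mapped to Up/Down in poor prognosis, sorted by q.

## Network reconstruction

MI between each TF and every other gene is estimated with a Gaussian
kernel density estimator after a copula (rank) transform to the unit
square, as the plug-in average `mean_i log[f2(u_i, v_i) / (f1(u_i) f1(v_i))]`,
clamped at zero.  The kernel width defaults to `0.25 n^{-1/6}` (caller
overridable): the `n^{-1/6}` rate is the standard two-dimensional
bandwidth scaling and the constant was fixed once for rank-uniform
marginals.  At n = 2000 the estimator is within ~0.05 nats of the
Gaussian closed form (see the validation battery); the residual bias is
the usual kernel-density boundary and smoothing bias and largely cancels
between numerator and denominator.

The MI threshold I0 is calibrated from a permutation null: `n_null_pairs`
random gene pairs with one member independently permuted, the upper tail
of the null fitted as `ln P(MI > m) = alpha - beta m` (top 25% of the
null sample), and I0 solving the fit at the requested significance
(default p = 0.05).  A degenerate fit (beta <= 0) falls back to the
empirical quantile with a warning.

DPI pruning removes, within every triangle of the *input* network, any
edge with `MI < (1 - tolerance) * min` of the other two (strict
comparison, so exact ties survive at the default tolerance 0; all checks
use input MI values and removals apply once at the end).  Note the
convention: tolerance 0 is the *strictest* setting; raising the tolerance
removes fewer edges.

The consensus network resamples samples with replacement `n_bootstrap`
times (workflow default 100; the bundled demo and validation battery use
25 to keep runtimes desk-scale) and reruns inference plus DPI per
replicate.  Two numerical points matter here:

* the MI threshold is recalibrated on each replicate's resampled data.
  Resampling duplicates samples, which inflates kernel MI estimates; a
  threshold calibrated once on the original data is then systematically
  too low and weakly-dependent pairs recur across replicates.
* edges are retained when their support count is significant under a
  Poisson null whose mean is the average support over all edges ever
  observed, at `consensus_alpha` (default 0.05) with Bonferroni correction
  over tested edges.  The support threshold is capped at `n_bootstrap`:
  an edge present in every replicate is always retained, because the
  Poisson mean degenerates when persistent edges dominate the observed
  edge set (small dense networks).

Consensus MI is the mean over supporting replicates; no re-estimation.
Per-replicate seeds derive deterministically from the master seed.

## Master regulator analysis

A TF's regulon is its set of network neighbors (edges are undirected; the
TF endpoint is the regulator, and a TF-TF edge puts each TF in the
other's regulon).  Enrichment of a regulon in the signature is a
one-sided Fisher's exact test (hypergeometric upper tail) over a
universe that defaults to the nodes of the network under test — the genes
that survived that cohort's filtering; an all-merged-genes universe is
available as a sensitivity option.  Candidates are flagged at
Bonferroni-corrected p <= alpha over the regulons tested; raw p-values are
reported alongside.  The `mode` column (+/-) is the TF's own DE direction
(+ = up in the unmutated group), an interpretive convention.

Specificity controls remove candidates that are (a) enriched for the
disease signature in the healthy-control network (whose couplings the
generator severs), or (b) enriched for a proliferation gene set within
the disease network.  The cross-network consensus keeps TFs significant
in at least `min_networks` (default 4) networks and pools the union of
their per-network targets.

## Survival evaluation

The gene-set association test is a permutation global test: with
`r` the martingale residuals of the covariate-free Cox null model
(event indicator minus Nelson-Aalen cumulative hazard at the subject's
time), the statistic is `Q = mean_g (z_g . r)^2` over row-standardized
genes, and the p-value is the tail probability of Q under residual
relabeling (`n_perm` permutations, +1-corrected so p >= 1/(n_perm+1)).
This replaces the asymptotic machinery of the classical global test with
an exact permutation reference; it is deterministic given the seed.

Per-gene screening is a univariate Cox fit per standardized gene
(Efron tie handling, Wald p, BH adjustment); non-converging genes are
flagged and excluded from reduction.

Profile reduction ("zooming" into the prognostic core) clusters genes
with distance `1 - |Pearson correlation|` and average linkage, then tests
branches top-down with the global test under an inheritance rule: a child
is tested only if its parent was significant, and the parent's alpha is
split between children proportionally to leaf counts.  Retained genes are
leaves whose entire ancestor chain (their own single-gene test included)
was significant, reported with the Cox coefficient sign (POS = higher
expression associated with longer survival, i.e. a negative log-hazard)
and BH-adjusted Cox p.  The inheritance rule is a simplified form of the
focus-level idea; the exact branch-testing procedure of the reference
workflow is not specified anywhere, so this is a documented stand-in.
Under the global null the root test alone controls the family: the
reduction returns an empty profile in ~95% of null datasets at alpha
0.05.

Classification comparisons fit a linear-kernel SVM (C = 1) on one
class-stratified train/test split shared by all feature sets, reporting
the test misclassification rate.  Stratification is a documented
deviation from plain random splitting, guaranteeing both labels on both
sides.  Group contrasts scale each gene by its grand mean (relative
expression, grand mean exactly 1) and apply two-sided pooled t-tests with
Bonferroni correction.

## Pipeline and problem sizes

`run_pipeline` chains ingest -> preprocess -> meta-analysis -> per-cohort
consensus networks -> MRA with controls and cross-network consensus ->
survival evaluation, writing every intermediate table plus a manifest
(parameters, derived seeds, per-stage counts).  All randomness flows from
one master seed through named substreams, so a run is a pure function of
its configuration.

The synthetic demo uses 5 cohorts of 60 + 60 samples over 600 genes with
10 planted TFs x 15 targets (overlap 0.2), 60 DE genes, 20 survival
genes, B = 25 bootstraps and 300-500 null pairs for threshold
calibration; the last two cohorts carry survival outcomes, and a
60-sample severed-coupling normal cohort serves as the control.  The
validation battery (`cllnet.validation`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) uses n = 2000 for
the Gaussian MI oracle, 1000 null pairs for threshold calibration, 100
random graphs for the DPI oracle, every 2x2 table with universe <= 60 for
the FET oracle, 2000 null genes (K = 5) for combination calibration,
5-10 seeds for network/MRA recovery, and 400/200/40 replicates for the
survival calibration checks.  These sizes are the package's chosen
trade-off between statistical resolution and a desk-scale runtime.

## Known limitations

* The kernel MI estimator is O(n^2) per pair; cohorts of thousands of
  samples would need subsampling or a binned estimator.
* The AW combination method's permutation null is approximate and limited
  to K <= 10 studies; it is flagged experimental.
* The Poisson consensus null is a pragmatic model of bootstrap edge
  support, not an exact test; its Bonferroni correction is conservative
  and the support-threshold cap is a documented boundary rule.
* Mode (+/-) assignment in MRA follows the TF's own DE direction; other
  platforms use four-way activation/repression modes, which are out of
  scope here.
* Real-data concerns — probe annotation, platform harmonization, VSN
  normalization, cohort quality control — are outside the package; inputs
  are assumed already variance-stabilized (an optional log2 flag exists
  for raw-scale data).
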