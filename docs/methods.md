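# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the design choices made where the procedure was genuinely open.

## Data model

A cohort is a set of linked layers sharing sample identifiers: a CpG × sample
beta-value matrix with per-probe annotation (chromosome, position, gene
symbol(s), exclusion flags), a sample sheet (MRI label, survival time in
months, event indicator, clinical covariates), an expression count matrix with
a gene→CpG map, probe-level copy-number log2-ratio tracks for tumors and
normal references, a long table of per-pipeline mutation calls, and a
sample × rater label matrix. Beta values are clipped into
`[1e-3, 1−1e-3]` at load time so M-values stay finite; all statistics on
methylation use M-values, all displays and probe selection use beta values.

## Preprocessing

Probes flagged as sex-chromosomal, SNP-overlapping or repetitive are removed
before any signature work (filtering precedes MAD selection; the order is
fixed in the pipeline configuration). Probe selection for unsupervised
analyses keeps the `mad_top` (default 30,000) probes with the largest median
absolute deviation of beta across samples, computed **without** the 1.4826
consistency constant — the raw median of absolute deviations — and with ties
broken lexicographically by probe id so the selection is reproducible.
Normalization is a no-op hook: raw-intensity normalization needs array-level
input that this package does not consume, so inputs are expected to be
normalized upstream.

## Signature discovery

1. **DMP testing.** Welch's two-sample t-test per CpG on M-values. Welch
   rather than a pooled-variance test because M-value variances routinely
   differ between groups; the choice is surfaced in the API. Probes with zero
   variance in both classes are flagged degenerate with p = 1 rather than
   dropped. DMPs are probes with `p < alpha` (default 0.001).
2. **Stability pruning.** Greedy leave-one-probe-out search: at each step the
   samples are 2-cluster clustered (Euclidean, complete linkage) with each
   single probe held out, clusters are mapped to MRI labels by majority, and
   the probe whose removal most reduces the misclassification rate is dropped
   (lexicographic tie-break); the loop stops when no single removal strictly
   reduces the error, or when fewer than two probes would remain. This is a
   deterministic operationalization of "prune until the clustering is
   stable"; it is intentionally myopic — a *block* of mutually reinforcing
   uninformative probes can survive if no single removal helps — which is the
   price of a reproducible rule.
3. **Random-forest ranking.** 500 trees, `sqrt(p)` features per split, fixed
   seed, mean-decrease-in-impurity importances, ties broken by probe id.
4. **Signature.** The top-15 probes. Training samples are clustered
   (Euclidean/complete, cut at 2), the cluster holding the majority of MRI
   SVZ+ samples is oriented to SVZ+ (a tie raises and requires an explicit
   override), and the per-class mean M-vectors are stored as centroids.

## Classification

Three modes. `train_clustering` re-clusters with Euclidean distance and
complete linkage; `validation_clustering` uses Chebyshev ("maximum") distance
with Ward linkage — the Ward update is applied to the Chebyshev distance
matrix directly, as in R's `hclust(..., method="ward.D")` tradition of
combining Ward with non-Euclidean distances; scipy emits a warning for this
combination, which is deliberately suppressed. Both cut at exactly two
clusters and orient each cluster by choosing the cluster→centroid assignment
minimizing the summed distance of cluster mean vectors to centroids (this
cancels cohort-level baseline shifts, making the orientation robust to batch
offsets between cohorts). `centroid` mode assigns each sample independently to
the nearest centroid; it reproduces the training clusters exactly but is
sensitive to cohort-level baseline differences, so it is not recommended
across cohorts.

## Survival

Kaplan–Meier product-limit estimates and medians per group. Cox PH fits use
Efron tie handling and report `exp(coef)` with 95% Wald intervals and a
likelihood-ratio test against the null model; perfect separation surfaces as
a convergence error, rank-deficient designs name the collinear columns.
Weibull fits are accelerated-failure-time maximum likelihood with right
censoring; covariate rows additionally report the PH-equivalent hazard ratio
`exp(−shape · β_AFT)`. Multivariable fits refuse to run below 5 events per
variable unless forced — parametric models help at small n but do not remove
the instability. Fitting is delegated to lifelines; an independent brute-force
partial-likelihood oracle in the test suite checks the Cox estimate, and a
closed-form exponential limit checks the Weibull fit.

## Categorical and agreement statistics

* Chi-squared: Pearson statistic, Yates continuity correction applied exactly
  when the table is 2×2 (the R `chisq.test` default convention); this
  reproduces the published patient-table p-values to two decimals, including
  the three-row tables (TMZ, MGMT) where the "Unsure" category is kept as a
  row.
* Fisher: two-sided hypergeometric tail sum.
* Barnard: unconditional exact test for 2×2 tables with fixed group (column)
  totals, using the Z-pooled score statistic; the p-value is the maximum over
  1001 equally spaced nuisance success probabilities in (0,1) of the total
  probability of tables at least as extreme (|Z| ordering). The fixed grid
  makes the maximization deterministic; it can sit marginally below the
  continuous supremum (observed ≤ ~3×10⁻³ against an optimizer-based
  implementation) and exactly matches an exhaustive enumeration oracle at the
  same grid.
* Goodman–Kruskal lambda: proportional reduction in prediction error, with a
  seeded percentile bootstrap (default 2000 resamples) over the underlying
  observation pairs; undefined (explicit marker) when the modal category
  already captures every observation.
* ICC(2,1): two-way random effects, absolute agreement, single rater, from
  ANOVA mean squares with the McGraw–Wong F-based interval; complete cases
  only; categorical SVZ labels are coded 0/1. The variant choice is exposed —
  published ICCs of this kind rarely state theirs.
* Consensus rating: unanimity of non-missing raters; anything else (including
  zero ratings) is no-consensus.
* Multiple testing: Benjamini–Hochberg step-up, with monotone adjusted values.

## Copy number

Segmentation is recursive binary splitting in the CBS family: the candidate
breakpoint maximizes the two-sample t-statistic between left and right probe
sets (at least `min_probes` = 5 on each side), the split is accepted when a
within-segment permutation test (199 permutations, seeded) gives
`p < alpha_split` = 0.01, and the procedure recurses per chromosome — it is a
deterministic, seeded approximation documented as such, not a reimplementation
of any published segmenter. Gain/loss thresholds are
`median ± k · 1.4826 · MAD` (k = 2.5) of the normal-reference segment means;
a zero MAD raises and suggests a quantile fallback. Group comparison assigns
each sample's state per fixed-width bin from the segment covering the bin
midpoint (bins whose midpoint no probe covers are dropped at bin
construction) and tests altered-vs-not × class per bin with Fisher's exact
test. Gene-level CNV calls are out of scope; the co-alteration analysis
accepts gene-level CNV input when the caller supplies gene intervals.

## Mutations

"Any type of mutation vs no/silent mutation": a (sample, gene) pair is
mutated when at least `min_pipelines` (default 3 of 4) pipelines report a
non-silent call. Silent filtering before or after consensus yields the same
indicator. Per-gene enrichment uses Barnard's test with BH adjustment (10%
FDR default for panel-style data) and flags genes mutated in exactly one
class as exclusive. Burden is the per-sample count of consensus-mutated
genes, compared by two-sided Wilcoxon rank-sum. The mutation-type × class
interaction fits `count ~ type * class` on per-(sample, type, pipeline)
non-silent call counts with a random intercept per calling pipeline (REML);
a singular random-effect variance — the expected outcome when pipelines
behave exchangeably — falls back to OLS with a warning. Counts are the
default response; a presence/absence response is exposed.

## Integrative omics

* **SAM.** `d_i = (mean_pos − mean_neg)/(s_i + s0)` with `s_i` the pooled
  two-sample SE and `s0` fixed at the median of the `s_i` — a deterministic
  simplification of the original coefficient-of-variation search whose
  calibration is verified empirically (null call budget) rather than assumed.
  Labels are permuted (seeded, default 500 permutations; 100 in the
  scaled-down analyses) and the expected order statistics `d̄₍ᵢ₎` computed; a
  probe is called at threshold Δ when `|d₍ᵢ₎ − d̄₍ᵢ₎| > Δ`, the FDR at Δ is
  the median across permutations of the number of null |d| beyond the call
  cutoff divided by the number called, and the smallest Δ meeting the target
  is chosen by a vectorized scan over the nested candidate call sets.
* **Consensus.** Intersection of the two cohorts' called sets with direction
  concordance enforced (a bare intersection is a config switch away but the
  concordant version is the default and the one tested).
* **Expression.** All transformed-value analyses use log2-CPM+1 — a monotone,
  variance-damping transform chosen over a regularized-log transform to avoid
  coupling the package to a specific external implementation. Differential
  expression is Welch's t per gene with BH control; the negative-binomial
  class contrast uses an NB2 likelihood with log total-count offset,
  method-of-moments dispersion start refined by MLE (Poisson GLM fallback on
  MLE failure), and a one-sided p defaulting to "lower in the positive class".
* **Pathways.** Score = Σ weight × z-scored log2-CPM over the pathway's
  genes; class contrast by OLS. Weight matrices are user-supplied files; the
  analysis scripts build a small synthetic weight table, as redistributing
  trained pathway weights is out of scope.

## Synthetic cohorts

The generator plants the exact structure the analysis assumes: two latent
classes (defaults 24 vs 30, the training-cohort design); per-CpG beta
distributions parameterized by (mean, concentration = 50) with a minority of
CpGs (default 200 of 10,000) shifted by `effect_delta` (default 0.25 on the
beta scale, ≈1.5 M-units at mid-range betas; 98% hypomethylated in the
positive class); Weibull survival (shape 1.4, scale 20 months ⇒ median ≈ 15.5
months in the negative class) with proportional hazards `exp(0.91)` ≈ 2.5 on
the class indicator and administrative uniform censoring whose upper bound is
solved numerically so the realized censoring fraction matches the target
(default 0.3); negative-binomial expression (mean 500, dispersion 0.1) with
coupled genes' log-means decreasing in their CpG's M-value, the slope
calibrated from the NB log-scale noise to hit the target correlation (−0.7)
and inflated by `1/(1−f)` to compensate for the attenuation CPM normalization
introduces when a fraction `f` of the library is itself class-coupled;
chromosome-level CNV shifts (−0.5 loss on chr10, +0.4 gain on chr19, planted
in the negative class at 0.7 penetrance, over probe noise of SD 0.1) plus
pure-noise normal references; per-gene class-dependent Bernoulli mutations
(background 0.10, enriched 0.35–0.40 vs 0.05, two class-exclusive genes at
0.15) observed by 4 pipelines at 0.9 sensitivity and 0.01 false-call rate
with 30% silent calls; and 3 raters who independently flip the true label
with probability 0.1. The sample sheet's MRI label is exact by default
(`mri_error` = 0), reflecting a training cohort restricted to
consensus-clear cases; no published noise model exists for MRI rating, so
rater error is a free parameter. All randomness flows from one seed through
named sub-streams, so bundles are byte-identical per configuration. A
validation cohort can be linked to a training bundle (same planted probe
positions and directions, independent draws); this emulates a shared
biological signal across cohorts but **not** batch effects, probe-type
chemistry, tumor purity, or cell-composition confounding — passing tests
demonstrate algorithmic correctness under the assumed model, not robustness
to real-array artifacts.

## Numerical choices and degenerate inputs

Beta↔M conversion uses the logistic form for numerical stability and rejects
values outside (0,1). Zero-variance features: flagged with p = 1 (t-tests),
NaN markers (correlations), skipped with a note (all-zero genes, empty
pathways). Cluster-orientation ties raise rather than guess. The Barnard and
BH implementations are exact, not approximations, so their tests assert
equality with enumeration oracles to 1e-12. Problem sizes in the analysis
scripts and acceptance checks (10,000 CpGs for discovery, 2,000 CpGs with
100 permutations for SAM calibration, 200 replicates at n = 300 for CI
coverage) were chosen as the smallest designs at which the planted effects
are comfortably identifiable; they are the package's stated study conditions,
not tuned quantities.

## Known limitations

Greedy stability pruning cannot dismantle coordinated decoy blocks (see
above). Centroid-mode classification is batch-sensitive across cohorts. The
segmentation stopping rule is permutation-based and therefore inherits
Monte-Carlo noise at boundary p-values (mitigated by seeding). The ICC
interval assumes the two-way random-effects model holds for 0/1-coded labels,
which is the field's common practice but a model approximation. Gene-level
CNV nomination and time-varying survival covariates are out of scope.
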