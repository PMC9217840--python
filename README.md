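# svzm — DNA-methylome classification of subventricular-zone glioblastoma

Glioblastomas that contact the subventricular zone (SVZ), the neural-stem-cell
niche lining the lateral ventricles, carry a worse prognosis than peripheral
tumors, but the MRI criteria used to call SVZ contact are subjective and
raters frequently disagree. `svzm` implements a DNA-methylation alternative:
starting from MRI-labelled cohorts profiled on 450K-style methylation arrays,
it derives a small CpG signature that separates SVZ+ from SVZ− tumors,
assigns any new cohort an "SVZM" class by hierarchical clustering over that
signature, validates the classification on overall survival, and characterizes
the two classes across copy number, mutations, expression and pathway
activity.

It is written for methods-oriented bioinformaticians: every stage is a plain
Python function over pandas containers, every stochastic step takes an
explicit seed, and a synthetic-cohort generator with planted ground truth
makes the whole pipeline testable without any external data.

## The model in brief

* **Signature discovery.** Beta values `β ∈ (0,1)` are converted to M-values
  `M = log2(β/(1−β))`. Per CpG, a Welch two-sample t-test on M-values against
  the MRI labels defines differentially methylated probes (DMPs, default
  `p < 0.001`). A greedy leave-one-probe-out pruning step drops probes whose
  removal reduces the 2-cluster (Euclidean, complete-linkage)
  misclassification against MRI, a random forest ranks the survivors by
  mean-decrease-in-impurity importance, and the top *k* = 15 CpGs form the
  signature with per-class centroid M-vectors.
* **Classification.** Samples are clustered over the signature probes
  (training: Euclidean/complete; validation: Chebyshev/Ward), the dendrogram
  is cut at two clusters, and each cluster takes the label of the nearest
  training centroid.
* **Survival.** Kaplan–Meier, Cox proportional hazards (Efron ties, Wald CIs,
  likelihood-ratio tests) and Weibull accelerated-failure-time fits, with an
  events-per-variable guard for multivariable models.
* **Categorical statistics.** Chi-squared (Yates on 2×2), Fisher exact, and
  Barnard's unconditional exact test (Z-pooled score statistic maximized over
  a 1001-point nuisance grid), Goodman–Kruskal lambda with bootstrap CI,
  ICC(2,1) from ANOVA mean squares, Benjamini–Hochberg FDR control.
* **Multi-omics.** SAM-style moderated d-statistics with permutation FDR and
  cross-cohort direction-concordant consensus; Welch-t differential expression
  on log2-CPM; methylation–expression Pearson correlation; negative-binomial
  class contrasts with a log library-size offset; weighted-z pathway scores.
  CNV segments come from CBS-style recursive binary splitting with permutation
  stopping, thresholded by `median ± 2.5 · 1.4826 · MAD` of normal-reference
  segment means. Mutation calls from four noisy pipelines are reduced by a
  ≥3-of-4 consensus before per-gene Barnard enrichment.

## Worked example

The numbered scripts under `analysis/` run the full two-cohort study on
synthetic data (cohort TSVs land in `scratch/`, result tables in `results/`):

```bash
python analysis/01_simulate.py            # 24+30 training, 50+50 validation
python analysis/02_discover_signature.py
python analysis/03_classify_and_survival.py
python analysis/04_rater_agreement.py
python analysis/05_cnv_profile.py
python analysis/06_mutation_enrichment.py
python analysis/07_integrate_omics.py
```

Output of the discovery and survival steps (seed 17):

```
DMPs at p<0.001: 207; after stability pruning: 207
signature: 15 CpGs
training: SVZM+ n=24, median OS 8.3 vs 16.5 months, Weibull HR 2.5 (LRT p=0.0084)
  univariable screen: significant covariates ['svzm_pos']
validation: SVZM+ n=50, median OS 9.5 vs 14.7 months, Weibull HR 3.04 (LRT p=9e-06)
```

The generator plants 200 differential CpGs among 10,000 and a log hazard
ratio of 0.91 for the SVZM+ class; the pipeline recovers a 15-CpG signature of
planted probes, classifies the held-out cohort, and estimates a hazard ratio
near the planted value. Downstream steps report the planted chr10/chr19 CNV
pattern, the enriched and class-exclusive mutated genes, a ~200-CpG
cross-cohort consensus that is 98% hypomethylated in SVZM+, and the
methylation-coupled expression program (median methylation–expression
correlation −0.72 among significant pairs).

The same workflow is exposed as a CLI (`svzm simulate|preprocess|discover|
classify|survival|agreement|cnv|mutations|integrate|all --outdir OUT --seed N`)
that writes a JSON manifest per stage.

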