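#!/usr/bin/env python
"""Integrative omics: consensus differential methylation, expression and
pathway activity by SVZM class.

Runs SAM (permutation FDR < 0.05) independently on training and validation
cohorts, intersects the called CpGs with direction concordance, ranks genes by
consensus-CpG count, tests differential expression (Welch t on log2-CPM, BH),
correlates methylation with expression for the mapped gene-CpG pairs,
intersects the gene-level calls of all three molecular layers, fits the
negative-binomial class contrast for the top-ranked genes and scores pathway
activity with a synthetic weight matrix.

Writes sam_consensus.tsv, gene_cpg_rank.tsv, differential_expression.tsv,
meth_expr_correlation.tsv, co_alteration.json, negbin_top_genes.tsv and
pathway_activity.tsv under results/.
"""

import argparse
import json

import numpy as np
import pandas as pd

from svzm.preprocess import read_methylation_tsv
from svzm.integration import (
    sam_test,
    consensus_dmp,
    differential_expression,
    meth_expr_correlation,
    gene_cpg_rank,
    co_alteration_intersect,
    negbin_expression_test,
    pathway_activity,
)


def _load(cohorts, name):
    m = read_methylation_tsv(f"{cohorts}/{name}/methylation.tsv",
                             f"{cohorts}/{name}/probe_annotation.tsv")
    counts = pd.read_csv(f"{cohorts}/{name}/expression.tsv", sep="\t", index_col=0)
    gmap = pd.read_csv(f"{cohorts}/{name}/gene_cpg_map.tsv", sep="\t")
    return m, counts, gmap


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohorts", default="scratch/cohorts")
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--n-perm", type=int, default=100)
    args = ap.parse_args()

    sams = {}
    for name in ("training", "validation"):
        m, _, _ = _load(args.cohorts, name)
        svzm = pd.read_csv(f"{args.outdir}/svzm_labels_{name}.tsv",
                           sep="\t").set_index("sample_id")["svzm_label"]
        sams[name] = sam_test(m.m_values(), svzm.loc[m.sample_ids],
                              n_perm=args.n_perm, seed=args.seed)
        print(f"{name}: SAM called {len(sams[name].called)} CpGs "
              f"(est. FDR {sams[name].fdr:.3f})")

    cons = consensus_dmp(sams["training"], sams["validation"])
    cons.to_csv(f"{args.outdir}/sam_consensus.tsv", sep="\t")
    frac_hypo = (cons["direction"] == "hypo_in_pos").mean()
    print(f"consensus: {len(cons)} CpGs, {frac_hypo:.0%} hypomethylated in SVZM+")

    m, counts, gmap = _load(args.cohorts, "validation")
    svzm = pd.read_csv(f"{args.outdir}/svzm_labels_validation.tsv",
                       sep="\t").set_index("sample_id")["svzm_label"]

    rank = gene_cpg_rank(list(cons.index), m.annotation)
    rank.rename("n_cpgs").to_csv(f"{args.outdir}/gene_cpg_rank.tsv", sep="\t",
                                 index_label="gene")
    top = [g for g in rank.index if g != "unannotated"][:5]
    print(f"top consensus genes by CpG count: {top}")

    de = differential_expression(counts, svzm.loc[counts.columns])
    de["table"].to_csv(f"{args.outdir}/differential_expression.tsv", sep="\t")
    n_up = int((de["deg"]["direction"] == "up_in_pos").sum())
    print(f"DEGs at 5% FDR: {len(de['deg'])} ({n_up} up in SVZM+); mean DEG "
          f"contrast {de['mean_deg_contrast_pos_minus_neg']:+.2f} log2-CPM")

    corr = meth_expr_correlation(m.m_values(), counts, gmap)
    corr.to_csv(f"{args.outdir}/meth_expr_correlation.tsv", sep="\t", index=False)
    sig_neg = corr[(corr["p"] < 0.01) & (corr["r"] < 0)]
    print(f"methylation-expression pairs with r<0 at p<0.01: {len(sig_neg)} "
          f"(median r {sig_neg['r'].median():+.2f})" if len(sig_neg)
          else "no significant negative methylation-expression correlations")

    # gene-level layer calls for the co-alteration intersection
    meth_genes = {}
    for p in cons.index:
        for g in filter(None, str(m.annotation.loc[p, "gene"]).split(";")):
            meth_genes[g] = ("hypo" if cons.loc[p, "direction"] == "hypo_in_pos"
                             else "hyper")
    expr_genes = {g: ("up" if d == "up_in_pos" else "down")
                  for g, d in de["deg"]["direction"].items()}
    cnv_genes = {}  # gene-level CNV calls require gene intervals; see methods
    inter = co_alteration_intersect(meth_genes, expr_genes, cnv_genes)
    with open(f"{args.outdir}/co_alteration.json", "w") as fh:
        json.dump({k: v.to_dict(orient="records") for k, v in inter.items()},
                  fh, indent=1)
    inverse = inter["MxE"]["category"].str.startswith("hypo_M/up_E").sum() \
        if len(inter["MxE"]) else 0
    print(f"methylation x expression co-altered genes: {len(inter['MxE'])} "
          f"({inverse} inverse hypo-M/up-E)")

    if top:
        nb = negbin_expression_test(counts, svzm.loc[counts.columns], genes=top)
        nb.to_csv(f"{args.outdir}/negbin_top_genes.tsv", sep="\t")
        print(f"neg-binomial one-sided p (lower in SVZM+) for top genes: "
              f"{dict(nb['one_sided_p'].round(3))}")

    # synthetic pathway weights: one pathway per block of coupled genes
    rng = np.random.default_rng(args.seed)
    genes = list(counts.index[:40])
    weights = pd.DataFrame({
        "pathway": ["COUPLED_SET"] * 20 + ["RANDOM_SET"] * 20,
        "gene": genes,
        "weight": np.concatenate([np.ones(20), rng.normal(0, 1, 20)]),
    })
    pa = pathway_activity(counts, weights, svzm.loc[counts.columns])
    pa.drop(columns="scores").to_csv(f"{args.outdir}/pathway_activity.tsv", sep="\t")
    for pw, row in pa.iterrows():
        print(f"pathway {pw}: contrast p={row['p']:.2g} "
              f"(mean score {row['mean_pos']:+.2f} SVZM+ vs "
              f"{row['mean_neg']:+.2f} SVZM-)")


if __name__ == "__main__":
    main()
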