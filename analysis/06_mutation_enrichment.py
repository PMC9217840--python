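#!/usr/bin/env python
"""Mutation landscape by SVZM class from multi-pipeline calls.

Applies the >=3-of-4 pipeline consensus ("any non-silent mutation vs no/silent
mutation"), Barnard per-gene enrichment with BH control at 10% FDR, the
Wilcoxon burden comparison and the mutation-type x class mixed-model
interaction (random intercept per calling pipeline).

Writes mutation_enrichment.tsv and mutation_type_interaction.tsv under results/.
"""

import argparse

import pandas as pd

from svzm.mutations import (
    pipeline_consensus,
    per_gene_enrichment,
    mutation_burden_test,
    mutation_type_interaction,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohorts", default="scratch/cohorts")
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--min-pipelines", type=int, default=3)
    ap.add_argument("--fdr", type=float, default=0.10)
    args = ap.parse_args()

    calls = pd.read_csv(f"{args.cohorts}/validation/mutations.tsv", sep="\t")
    svzm = pd.read_csv(f"{args.outdir}/svzm_labels_validation.tsv",
                       sep="\t").set_index("sample_id")["svzm_label"]
    pipelines = sorted(calls["pipeline"].unique())

    cons = pipeline_consensus(calls, list(svzm.index), pipelines,
                              min_pipelines=args.min_pipelines)
    enr = per_gene_enrichment(cons, svzm, q=args.fdr)
    enr.to_csv(f"{args.outdir}/mutation_enrichment.tsv", sep="\t")

    exclusive = enr[enr["exclusive"]]
    signif = enr[enr["significant"]]
    print(f"{len(enr)} genes with consensus mutations; "
          f"{len(signif)} enriched at {args.fdr:.0%} FDR; "
          f"{len(exclusive)} class-exclusive")
    for g, row in signif.iterrows():
        print(f"  {g}: {row['mut_pos']}/{row['n_pos']} SVZM+ vs "
              f"{row['mut_neg']}/{row['n_neg']} SVZM- "
              f"(Barnard p={row['barnard_p']:.2g}, towards {row['direction']})")

    burden = mutation_burden_test(cons, svzm)
    print(f"burden (non-silent consensus mutations/sample): "
          f"Wilcoxon p={burden['p']:.2g}")

    inter = mutation_type_interaction(calls, svzm)
    inter.to_csv(f"{args.outdir}/mutation_type_interaction.tsv", sep="\t")
    flagged = inter[inter["flagged"]].index.tolist()
    print(f"mutation-type x class interactions flagged: {flagged or 'none'}")


if __name__ == "__main__":
    main()
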