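#!/usr/bin/env python
"""Derive the SVZM signature from the training cohort.

Steps: probe filtering (sex chromosomes / SNP overlap / repeats), top-MAD
probe selection, per-CpG Welch t-tests on M-values against the MRI labels
(DMPs at p < 0.001), greedy clustering-stability pruning, random-forest
importance ranking, top-15 signature with training centroids.

Writes signature.json, dmp_table.tsv and gene_cpg_counts.tsv under results/.
"""

import argparse

import pandas as pd

from svzm.preprocess import read_methylation_tsv, filter_probes, top_mad_probes
from svzm.signature import discover_signature, gene_cpg_count


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohorts", default="scratch/cohorts")
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--mad-top", type=int, default=30_000)
    args = ap.parse_args()

    m = read_methylation_tsv(f"{args.cohorts}/training/methylation.tsv",
                             f"{args.cohorts}/training/probe_annotation.tsv")
    samples = pd.read_csv(f"{args.cohorts}/training/samples.tsv", sep="\t")
    labels = samples.set_index("sample_id")["mri_label"]

    m = filter_probes(m)
    m = top_mad_probes(m, min(args.mad_top, m.n_probes))
    sig, dmp, stable = discover_signature(m, labels, seed=args.seed)

    sig.to_json(f"{args.outdir}/signature.json")
    dmp.to_csv(f"{args.outdir}/dmp_table.tsv", sep="\t")
    counts = gene_cpg_count(sig, m.annotation)
    counts.rename("n_cpgs").to_csv(f"{args.outdir}/gene_cpg_counts.tsv",
                                   sep="\t", index_label="gene")

    n_dmp = int(dmp["is_dmp"].sum())
    print(f"DMPs at p<0.001: {n_dmp}; after stability pruning: {len(stable)}")
    print(f"signature: {len(sig.signature_probes)} CpGs")
    if len(counts):
        print(f"most represented gene: {counts.index[0]} ({counts.iloc[0]} CpGs)")


if __name__ == "__main__":
    main()
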