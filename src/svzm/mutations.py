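"""Multi-pipeline mutation-call consensus and class enrichment.

A (sample, gene) pair counts as mutated when at least ``min_pipelines`` of the
calling pipelines report a non-silent variant there ("any type of mutation vs
no/silent mutation"). Per-gene enrichment between classes uses Barnard's
unconditional exact test; per-sample burden is compared by a two-sided
Wilcoxon rank-sum test; mutation-type x class interactions are modeled with a
linear mixed model carrying a random intercept per calling pipeline.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from svzm.catstats import barnard_test, bh_fdr
from svzm.util import two_classes

log = logging.getLogger(__name__)

VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "frameshift_ins",
    "frameshift_del",
    "inframe_del",
    "splice_region",
    "splice_site",
    "silent",
    "other",
)


def _validate_calls(calls: pd.DataFrame, pipelines=None) -> pd.DataFrame:
    bad = set(calls["variant_class"].unique()) - set(VARIANT_CLASSES)
    if bad:
        raise ValueError(f"unknown variant classes: {sorted(bad)}")
    if pipelines is not None:
        unknown = set(calls["pipeline"].unique()) - set(pipelines)
        if unknown:
            raise ValueError(f"unknown pipeline ids: {sorted(unknown)}")
    return calls


def filter_silent(calls: pd.DataFrame) -> pd.DataFrame:
    """Drop records whose variant class is silent; everything else unchanged."""
    _validate_calls(calls)
    return calls[calls["variant_class"] != "silent"].reset_index(drop=True)


def pipeline_consensus(
    calls: pd.DataFrame,
    samples: list,
    pipelines: list,
    min_pipelines: int = 3,
) -> pd.DataFrame:
    """Consensus mutation indicator per (sample, gene).

    A pair is mutated iff >= ``min_pipelines`` distinct pipelines report a
    non-silent call for it. Returns a long table (sample_id, gene, n_calls,
    mutated) covering every (sample, gene-with-any-call) pair.
    """
    if min_pipelines > len(pipelines):
        raise ValueError("min_pipelines exceeds number of pipelines")
    _validate_calls(calls, pipelines)
    nonsilent = calls[calls["variant_class"] != "silent"]
    counts = (
        nonsilent.groupby(["sample_id", "gene"])["pipeline"]
        .nunique()
        .rename("n_calls")
        .reset_index()
    )
    genes = sorted(calls["gene"].unique())
    full = pd.MultiIndex.from_product([samples, genes], names=["sample_id", "gene"])
    out = counts.set_index(["sample_id", "gene"]).reindex(full, fill_value=0).reset_index()
    out["mutated"] = out["n_calls"] >= min_pipelines
    return out


def per_gene_enrichment(consensus: pd.DataFrame, labels: pd.Series, q: float = 0.05) -> pd.DataFrame:
    """Barnard enrichment of consensus mutations per gene between the classes.

    Genes with zero consensus mutations are skipped (noted). Output columns:
    counts per class, barnard_p, BH-adjusted p, direction (class with the
    higher mutation frequency) and an ``exclusive`` flag for genes mutated in
    exactly one class.
    """
    labels, classes = two_classes(labels)
    if (labels == classes[0]).sum() == 0 or (labels == classes[1]).sum() == 0:
        raise ValueError("need two non-empty classes")
    n_pos = int((labels == classes[0]).sum())
    n_neg = int((labels == classes[1]).sum())
    rows = []
    for gene, sub in consensus.groupby("gene"):
        sub = sub.set_index("sample_id")
        mut = sub["mutated"]
        m_pos = int(mut[labels[labels == classes[0]].index].sum())
        m_neg = int(mut[labels[labels == classes[1]].index].sum())
        if m_pos + m_neg == 0:
            log.info("gene %s has no consensus mutations; skipped", gene)
            continue
        table = [[m_pos, m_neg], [n_pos - m_pos, n_neg - m_neg]]
        p = barnard_test(table)
        f_pos, f_neg = m_pos / n_pos, m_neg / n_neg
        rows.append(
            {
                "gene": gene,
                "mut_pos": m_pos,
                "mut_neg": m_neg,
                "n_pos": n_pos,
                "n_neg": n_neg,
                "barnard_p": p,
                "direction": classes[0] if f_pos >= f_neg else classes[1],
                "exclusive": (m_pos == 0) != (m_neg == 0),
            }
        )
    if not rows:
        return pd.DataFrame()
    out = pd.DataFrame(rows).set_index("gene")
    adj = bh_fdr(out["barnard_p"], q=q)
    out["p_adj"] = adj["p_adj"].values
    out["significant"] = adj["significant"].values
    return out


def mutation_burden_test(consensus: pd.DataFrame, labels: pd.Series) -> dict:
    """Per-sample non-silent consensus mutation counts, compared between the
    classes with a two-sided Wilcoxon rank-sum test."""
    labels, classes = two_classes(labels)
    counts = consensus.groupby("sample_id")["mutated"].sum()
    counts = counts.reindex(labels.index, fill_value=0)
    a = counts[labels == classes[0]].values
    b = counts[labels == classes[1]].values
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 samples per class")
    if np.ptp(np.concatenate([a, b])) == 0:
        log.warning("all burden counts tied; p set to 1")
        return {"counts": counts, "statistic": np.nan, "p": 1.0}
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"counts": counts, "statistic": float(res.statistic), "p": float(res.pvalue)}


def mutation_type_interaction(
    calls: pd.DataFrame, labels: pd.Series, response: str = "counts"
) -> pd.DataFrame:
    """Mutation-type x class interaction with a random intercept per pipeline.

    Builds per (sample, variant type, pipeline) non-silent call counts (or a
    presence indicator when ``response='presence'``) and fits
    ``value ~ type * class`` with a pipeline random intercept (REML). Falls
    back to OLS with a warning when the random-effect variance is singular.
    Returns the per-type class-interaction coefficient, SE and Wald p, with
    the reference type being the first observed type alphabetically.
    """
    labels, classes = two_classes(labels)
    nonsilent = calls[calls["variant_class"] != "silent"]
    types = sorted(nonsilent["variant_class"].unique())
    dropped = sorted(set(VARIANT_CLASSES) - {"silent"} - set(types))
    if dropped:
        log.info("types absent from data dropped: %s", dropped)
    pipelines = sorted(calls["pipeline"].unique())
    grid = pd.MultiIndex.from_product(
        [labels.index, types, pipelines], names=["sample_id", "vtype", "pipeline"]
    )
    counts = (
        nonsilent.groupby(["sample_id", "variant_class", "pipeline"])
        .size()
        .rename("value")
        .reindex(grid, fill_value=0)
        .reset_index()
    )
    if response == "presence":
        counts["value"] = (counts["value"] > 0).astype(float)
    counts["pos"] = (labels.loc[counts["sample_id"]].values == classes[0]).astype(float)

    formula = "value ~ C(vtype) * pos"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm(formula, counts, groups=counts["pipeline"])
        try:
            fit = md.fit(reml=True)
            cov_re = np.asarray(fit.cov_re.values, dtype=float)
            singular = (not np.isfinite(cov_re).all()) or (cov_re <= 1e-10).all()
        except (np.linalg.LinAlgError, ValueError):
            fit, singular = None, True
        if fit is None or singular:
            log.warning(
                "pipeline random-effect variance singular or fit failed; "
                "falling back to fixed-effects OLS"
            )
            fit = smf.ols(formula, counts).fit()

    rows = []
    ref = types[0]
    for t in types:
        if t == ref:
            term = "pos"  # class effect at the reference type
        else:
            term = f"C(vtype)[T.{t}]:pos"
        if term not in fit.params.index:
            continue
        rows.append(
            {
                "vtype": t,
                "term": term,
                "coef": float(fit.params[term]),
                "se": float(fit.bse[term]),
                "p": float(fit.pvalues[term]),
            }
        )
    out = pd.DataFrame(rows).set_index("vtype")
    out["flagged"] = out["p"] < 0.05
    return out
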