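"""Integrative omics: SAM-style permutation-FDR differential methylation,
cross-cohort consensus, differential expression, methylation-expression
correlation, gene-level CpG ranking, co-alteration intersection,
negative-binomial expression testing and pathway-activity scoring.

The SAM statistic is ``d_i = (mean_pos - mean_neg) / (s_i + s0)`` with ``s_i``
the pooled two-sample standard error and the fudge factor ``s0`` fixed at the
median of the ``s_i``. Significance is declared on the order-statistic scale:
a probe is called when its sorted ``d`` deviates from the permutation-expected
order statistic by more than a threshold ``delta``, and the reported FDR at
``delta`` is the median across permutations of the number of null |d| values
beyond the call cutoff, divided by the number called.

Expression analyses use log2-CPM(+1) as the variance-damping transform of raw
counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from svzm.catstats import bh_fdr
from svzm.util import two_classes

log = logging.getLogger(__name__)


def log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(counts / library_size * 1e6 + 1) per sample."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("sample with zero total counts")
    return np.log2(counts / totals * 1e6 + 1.0)


_two_classes = two_classes


# ---------------------------------------------------------------------------
# SAM

@dataclass
class SamResult:
    d: pd.Series  # per-probe d statistic
    s0: float
    delta: float
    called: list  # probe ids
    fdr: float
    direction: pd.Series = field(default=None)  # hypo_in_pos / hyper_in_pos


def _d_stat(X: np.ndarray, pos: np.ndarray, s0: float | None = None):
    """SAM d statistic for each row of X; pos is the boolean class mask."""
    x, y = X[:, pos], X[:, ~pos]
    n1, n2 = x.shape[1], y.shape[1]
    diff = x.mean(axis=1) - y.mean(axis=1)
    pooled = ((x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1))
              / (n1 + n2 - 2))
    s = np.sqrt(np.maximum(pooled, 0.0) * (1 / n1 + 1 / n2))
    if s0 is None:
        s0 = float(np.median(s))
    return diff / (s + s0), s0


def sam_test(
    values: pd.DataFrame,
    labels,
    n_perm: int = 500,
    fdr_target: float = 0.05,
    seed: int = 0,
) -> SamResult:
    """Two-class SAM on a feature x sample matrix (M-values for methylation).

    See the module docstring for the statistic, calling rule and FDR
    definition. Returns the smallest ``delta`` whose estimated FDR is at or
    below ``fdr_target`` (empty call set, delta=inf, FDR 0 when none exists).
    """
    labels, classes = _two_classes(labels)
    pos = (labels == classes[0]).values
    if pos.sum() < 3 or (~pos).sum() < 3:
        raise ValueError("each class needs >= 3 samples for SAM")
    if n_perm < 50:
        log.warning("n_perm=%d is low; FDR estimates will be unstable", n_perm)
    X = values.values.astype(float)
    d, s0 = _d_stat(X, pos)
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]

    rng = np.random.default_rng(seed)
    n = X.shape[1]
    perm_sorted = np.empty((n_perm, X.shape[0]))
    for b in range(n_perm):
        perm = rng.permutation(n)
        d_b, _ = _d_stat(X[:, perm], pos, s0=s0)
        perm_sorted[b] = np.sort(d_b)
    dbar = perm_sorted.mean(axis=0)
    dev = np.abs(d_sorted - dbar)

    # scan candidate deltas (ascending); called sets are nested and shrink as
    # delta grows, so cut thresholds are suffix minima over dev-sorted probes
    cand = np.unique(dev)
    dev_order = np.argsort(dev, kind="stable")
    dev_asc = dev[dev_order]
    absd_asc = np.abs(d_sorted)[dev_order]
    suffix_min = np.minimum.accumulate(absd_asc[::-1])[::-1]
    first_idx = np.searchsorted(dev_asc, cand, side="right")
    valid = first_idx < dev.size
    cand, first_idx = cand[valid], first_idx[valid]
    n_called_all = dev.size - first_idx
    cuts = suffix_min[first_idx]
    abs_perm_sorted = np.sort(np.abs(perm_sorted), axis=1)
    null_counts = np.empty((n_perm, cand.size))
    for b in range(n_perm):
        null_counts[b] = perm_sorted.shape[1] - np.searchsorted(
            abs_perm_sorted[b], cuts, side="left"
        )
    fdr_all = np.median(null_counts, axis=0) / n_called_all
    hits = np.nonzero(fdr_all <= fdr_target)[0]
    best = None
    if hits.size:
        j = int(hits[0])
        delta = float(cand[j])
        called_mask = dev > delta
        best = (delta, called_mask, float(min(fdr_all[j], 1.0)))
    if best is None:
        return SamResult(
            d=pd.Series(d, index=values.index), s0=s0, delta=float("inf"),
            called=[], fdr=0.0,
            direction=pd.Series(np.where(d < 0, "hypo_in_pos", "hyper_in_pos"),
                                index=values.index),
        )
    delta, called_mask, fdr = best
    called_ids = list(values.index[order[called_mask]])
    return SamResult(
        d=pd.Series(d, index=values.index),
        s0=s0,
        delta=delta,
        called=called_ids,
        fdr=fdr,
        direction=pd.Series(np.where(d < 0, "hypo_in_pos", "hyper_in_pos"),
                            index=values.index),
    )


def consensus_dmp(sam_a: SamResult, sam_b: SamResult) -> pd.DataFrame:
    """Cross-cohort consensus: intersection of called sets with concordant
    direction. Reports each probe's per-cohort d and the shared direction."""
    if len(sam_a.d.index.intersection(sam_b.d.index)) == 0:
        raise ValueError("SAM results share no probes")
    common = [p for p in sam_a.called if p in set(sam_b.called)]
    rows = []
    for p in common:
        da, db = sam_a.d[p], sam_b.d[p]
        if np.sign(da) != np.sign(db):
            continue
        rows.append(
            {"probe_id": p, "d_a": da, "d_b": db,
             "direction": "hypo_in_pos" if da < 0 else "hyper_in_pos"}
        )
    return pd.DataFrame(rows, columns=["probe_id", "d_a", "d_b", "direction"]).set_index(
        "probe_id"
    )


# ---------------------------------------------------------------------------
# Expression

def differential_expression(counts: pd.DataFrame, labels, fdr: float = 0.05) -> dict:
    """Per-gene Welch t-test on log2-CPM with BH control.

    Returns the full table, the DEG set with directions (up/down in the
    positive class), and the mean-expression group contrast over the DEG set.
    """
    labels, classes = _two_classes(labels)
    vals = log_cpm(counts)
    pos = (labels == classes[0]).values
    x, y = vals.values[:, pos], vals.values[:, ~pos]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(x, y, axis=1, equal_var=False)
    stat = np.asarray(res.statistic, float)
    p = np.asarray(res.pvalue, float)
    flat = ~np.isfinite(stat)
    stat[flat] = 0.0
    p[flat] = 1.0
    table = pd.DataFrame(
        {
            "mean_pos": x.mean(axis=1),
            "mean_neg": y.mean(axis=1),
            "statistic": stat,
            "p": p,
            "constant": flat,
        },
        index=counts.index,
    )
    adj = bh_fdr(table["p"], q=fdr)
    table["p_adj"] = adj["p_adj"].values
    table["significant"] = adj["significant"].values
    table["direction"] = np.where(table["mean_pos"] > table["mean_neg"], "up_in_pos", "down_in_pos")
    deg = table[table["significant"]]
    if len(deg):
        contrast = float((deg["mean_pos"] - deg["mean_neg"]).mean())
    else:
        contrast = float("nan")
    return {"table": table, "deg": deg, "mean_deg_contrast_pos_minus_neg": contrast}


def meth_expr_correlation(
    m_values: pd.DataFrame, counts: pd.DataFrame, gene_cpg_map: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation between each mapped CpG's M-value and its gene's
    log2-CPM across shared samples; two-sided p. Zero-variance pairs are
    returned with an undefined (NaN) marker."""
    shared = [s for s in m_values.columns if s in counts.columns]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    expr = log_cpm(counts[shared])
    rows = []
    for _, rec in gene_cpg_map.iterrows():
        cpg, gene = rec["cpg_id"], rec["gene"]
        if cpg not in m_values.index or gene not in expr.index:
            continue
        mv = m_values.loc[cpg, shared].values.astype(float)
        ev = expr.loc[gene].values.astype(float)
        if np.std(mv) == 0 or np.std(ev) == 0:
            rows.append({"gene": gene, "cpg_id": cpg, "r": np.nan, "p": np.nan, "n": len(shared)})
            continue
        r, p = stats.pearsonr(mv, ev)
        rows.append({"gene": gene, "cpg_id": cpg, "r": float(r), "p": float(p), "n": len(shared)})
    return pd.DataFrame(rows)


def gene_cpg_rank(consensus_probes, annotation: pd.DataFrame) -> pd.Series:
    """Rank genes by how many consensus CpGs annotate to them, descending
    (ties by symbol). CpGs with a ';'-joined multi-gene annotation increment
    every listed gene (nested/overlapping pairs); unannotated CpGs are counted
    under ``"unannotated"``."""
    counts: dict = {}
    for p in consensus_probes:
        genes = str(annotation.loc[p, "gene"]) if p in annotation.index else ""
        targets = [g for g in genes.split(";") if g] or ["unannotated"]
        for g in targets:
            counts[g] = counts.get(g, 0) + 1
    if not counts:
        return pd.Series(dtype=int)
    s = pd.Series(counts, dtype=int)
    order = pd.DataFrame({"n": -s, "g": s.index.astype(str)})
    return s.loc[order.sort_values(["n", "g"], kind="stable").index]


def co_alteration_intersect(
    meth_genes: dict, expr_genes: dict, cnv_genes: dict
) -> dict:
    """Pairwise intersections of gene-level calls from the three layers.

    Inputs map gene -> direction (methylation: ``hypo``/``hyper``; expression:
    ``up``/``down``; CNV: ``gain``/``loss``). Returns, for each layer pair, a
    DataFrame of shared genes with the direction-combination category
    (e.g. ``hypo_M/up_E``). Symmetric in layer order.
    """
    layers = {"M": meth_genes, "E": expr_genes, "CN": cnv_genes}
    out = {}
    for a, b in (("M", "E"), ("M", "CN"), ("E", "CN")):
        ga, gb = layers[a], layers[b]
        rows = [
            {"gene": g, "category": f"{ga[g]}_{a}/{gb[g]}_{b}"}
            for g in sorted(set(ga) & set(gb))
        ]
        out[f"{a}x{b}"] = pd.DataFrame(rows, columns=["gene", "category"])
    return out


def negbin_expression_test(
    counts: pd.DataFrame,
    labels,
    genes: list | None = None,
    direction: str = "less",
) -> pd.DataFrame:
    """Per-gene negative-binomial regression of counts on class with a
    log(total counts) offset.

    Dispersion starts at a method-of-moments estimate and is refined by
    maximum likelihood. ``direction='less'`` reports the one-sided p for
    decreased expression in the positive class ('greater' for the opposite).
    All-zero genes are skipped.
    """
    labels, classes = _two_classes(labels)
    genes = list(genes) if genes is not None else list(counts.index)
    pos = (labels == classes[0]).astype(float).values
    offset = np.log(counts.sum(axis=0).values.astype(float))
    X = sm.add_constant(pos)
    rows = []
    for g in genes:
        y = counts.loc[g].values.astype(float)
        if y.sum() == 0:
            log.info("gene %s all-zero; skipped", g)
            continue
        # method-of-moments NB2 alpha on rate-normalized counts
        mu0 = max(y.mean(), 1e-8)
        alpha0 = max((y.var(ddof=1) - mu0) / mu0**2, 1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = sm.NegativeBinomial(y, X, offset=offset)
                fit = model.fit(start_params=[np.log(mu0) - offset.mean(), 0.0, alpha0],
                                disp=False, maxiter=200)
                coef = float(fit.params[1])
                se = float(fit.bse[1])
            except Exception:  # fall back to Poisson GLM when NB MLE fails
                fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
                coef = float(fit.params[1])
                se = float(fit.bse[1])
        z = coef / se if se > 0 else 0.0
        if direction == "less":
            p = float(stats.norm.cdf(z))
        elif direction == "greater":
            p = float(stats.norm.sf(z))
        else:
            raise ValueError("direction must be 'less' or 'greater'")
        rows.append({"gene": g, "coef": coef, "se": se, "one_sided_p": p})
    return pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame()


def pathway_activity(
    counts: pd.DataFrame, weights: pd.DataFrame, labels
) -> pd.DataFrame:
    """Weighted-sum pathway activity scores with a two-group linear-model contrast.

    ``weights`` has columns (pathway, gene, weight). Per sample,
    score = sum_g w_g * z(log2-CPM_g); pathways without overlapping genes are
    skipped; all-zero weights yield an undefined (NaN) contrast p.
    """
    labels, classes = _two_classes(labels)
    vals = log_cpm(counts)
    sd = vals.std(axis=1, ddof=1)
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    pos = (labels == classes[0]).astype(float).values
    rows = []
    for pw, sub in weights.groupby("pathway"):
        overlap = sub[sub["gene"].isin(z.index)]
        if overlap.empty:
            log.info("pathway %s has no overlapping genes; skipped", pw)
            continue
        w = overlap.set_index("gene")["weight"].astype(float)
        scores = w @ z.loc[w.index]
        if np.allclose(w.values, 0) or np.std(scores.values) == 0:
            rows.append({"pathway": pw, "mean_pos": 0.0, "mean_neg": 0.0,
                         "coef": 0.0, "p": np.nan,
                         "scores": scores})
            continue
        X = sm.add_constant(pos)
        fit = sm.OLS(scores.values, X).fit()
        rows.append(
            {
                "pathway": pw,
                "mean_pos": float(scores.values[pos == 1].mean()),
                "mean_neg": float(scores.values[pos == 0].mean()),
                "coef": float(fit.params[1]),
                "p": float(fit.pvalues[1]),
                "scores": scores,
            }
        )
    return pd.DataFrame(rows).set_index("pathway") if rows else pd.DataFrame()
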