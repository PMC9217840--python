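"""Discovery of the SVZ methylome (SVZM) signature and cluster-based classification.

Pipeline: per-CpG Welch t-tests on M-values against the MRI labels (DMPs at
p < alpha, default 0.001) -> greedy clustering-stability pruning -> random-forest
importance ranking -> top-k signature (default k=15) with stored training
centroids -> hierarchical-clustering classification of any cohort carrying the
signature probes.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import pdist, cdist
from sklearn.ensemble import RandomForestClassifier

from svzm.preprocess import MethylationMatrix
from svzm.simulate import POS, NEG
from svzm.util import two_classes

log = logging.getLogger(__name__)

TRAIN_LINKAGE = {"metric": "euclidean", "linkage": "complete"}
VALID_LINKAGE = {"metric": "chebyshev", "linkage": "ward"}


def _check_labels(labels, sample_ids) -> pd.Series:
    labels = pd.Series(labels)
    if len(labels) != len(sample_ids):
        raise ValueError("labels length does not match samples")
    labels.index = sample_ids
    two_classes(labels)
    return labels


def differential_methylation(
    m: MethylationMatrix, labels, alpha: float = 0.001
) -> pd.DataFrame:
    """Per-probe Welch two-sample t-test on M-values between the two label classes.

    Returns a DataFrame indexed by probe id with columns ``mean_pos``,
    ``mean_neg`` (M-value class means; "pos" is the SVZ+ class), ``statistic``,
    ``p_value``, ``direction`` (``hypo_in_pos``/``hyper_in_pos``),
    ``degenerate`` and ``is_dmp`` (p < alpha). Zero-variance-in-both-classes
    probes are flagged degenerate with p=1.
    """
    labels = _check_labels(labels, m.sample_ids)
    _, (pos_label, neg_label) = two_classes(labels)
    mv = m.m_values()
    x = mv.loc[:, (labels == pos_label).values].values
    y = mv.loc[:, (labels == neg_label).values].values
    if x.shape[1] < 2 or y.shape[1] < 2:
        raise ValueError("each class needs at least 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(x, y, axis=1, equal_var=False)
    stat = np.asarray(res.statistic, dtype=float)
    pval = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(stat)
    stat[degenerate] = 0.0
    pval[degenerate] = 1.0
    mean_pos = x.mean(axis=1)
    mean_neg = y.mean(axis=1)
    out = pd.DataFrame(
        {
            "mean_pos": mean_pos,
            "mean_neg": mean_neg,
            "statistic": stat,
            "p_value": pval,
            "direction": np.where(mean_pos < mean_neg, "hypo_in_pos", "hyper_in_pos"),
            "degenerate": degenerate,
        },
        index=m.probe_ids,
    )
    out["is_dmp"] = out["p_value"] < alpha
    return out


def _cluster_cut2(X: np.ndarray, metric: str, method: str) -> np.ndarray:
    """2-cluster hierarchical clustering of rows of X; returns labels in {0,1}."""
    if X.shape[0] < 2:
        return np.zeros(X.shape[0], dtype=int)
    d = pdist(X, metric=metric)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # ward on non-euclidean distances is intended
        Z = linkage(d, method=method)
    return fcluster(Z, t=2, criterion="maxclust") - 1


def _majority_error(cluster: np.ndarray, labels: np.ndarray) -> float:
    """Misclassification rate after mapping each cluster to its majority label."""
    err = 0
    for c in np.unique(cluster):
        sub = labels[cluster == c]
        vals, counts = np.unique(sub, return_counts=True)
        err += sub.size - counts.max()
    return err / labels.size


def stability_subset(m_dmp: MethylationMatrix, mri_labels) -> list:
    """Greedy leave-one-probe-out pruning of a DMP set for clustering stability.

    At each step, samples are 2-cluster hierarchically clustered (Euclidean,
    complete linkage, M-values) with each single probe left out; the probe
    whose removal most reduces majority-mapped misclassification against the
    MRI labels is dropped. Stops when no removal strictly reduces the error,
    or when fewer than 2 probes would remain.
    """
    labels = _check_labels(mri_labels, m_dmp.sample_ids).values
    mv = m_dmp.m_values()
    current = list(m_dmp.probe_ids)
    if len(current) < 2:
        log.warning("stability_subset: fewer than 2 probes; returning input unchanged")
        return current

    def err_for(probes):
        X = mv.loc[probes].values.T  # samples x probes
        return _majority_error(_cluster_cut2(X, "euclidean", "complete"), labels)

    cur_err = err_for(current)
    while len(current) > 2:
        errs = {p: err_for([q for q in current if q != p]) for p in current}
        best_err = min(errs.values())
        if best_err >= cur_err:
            break
        # deterministic tie-break: lexicographically smallest probe id
        best_probe = min(p for p, e in errs.items() if e == best_err)
        current.remove(best_probe)
        cur_err = best_err
    return current


def rf_rank(
    m_subset: MethylationMatrix,
    mri_labels,
    n_trees: int = 500,
    seed: int = 0,
) -> pd.Series:
    """Random-forest (mean-decrease-in-impurity) importance ranking of probes.

    Returns a Series of importances indexed by probe id, sorted descending
    with ties broken by probe id; deterministic given ``seed``.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    labels = _check_labels(mri_labels, m_subset.sample_ids)
    X = m_subset.m_values().values.T
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    rf.fit(X, labels.values)
    imp = pd.Series(rf.feature_importances_, index=m_subset.probe_ids, name="importance")
    order = pd.DataFrame({"imp": -imp, "pid": imp.index.astype(str)})
    return imp.loc[order.sort_values(["imp", "pid"], kind="stable").index]


@dataclass
class SignatureModel:
    """A k-CpG SVZM signature: ordered probes, importances, training centroids
    (mean M-value vectors per class) and the linkage specifications used for
    training- and validation-cohort clustering."""

    signature_probes: list
    importance: dict
    centroids: dict  # label -> list of mean M-values over signature probes
    train_linkage: dict
    valid_linkage: dict
    orientation: dict  # cluster index (str) -> label, from training

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def select_signature(
    ranked: pd.Series,
    m: MethylationMatrix,
    mri_labels,
    k: int = 15,
    orientation_override: dict | None = None,
) -> SignatureModel:
    """Take the top-k ranked probes and fit the training clustering.

    Samples are 2-cluster clustered (Euclidean, complete) over the signature
    probes' M-values; the cluster holding the majority of MRI SVZ+ samples is
    oriented to SVZ+. A majority tie raises unless ``orientation_override``
    maps cluster index ('0'/'1') to labels explicitly. Per-class centroids are
    the mean M-vectors of the oriented clusters.
    """
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds ranking length {len(ranked)}")
    probes = list(ranked.index[:k])
    labels = _check_labels(mri_labels, m.sample_ids)
    _, (pos_label, _neg) = two_classes(labels)
    mv = m.subset_probes(probes).m_values()
    X = mv.values.T
    cl = _cluster_cut2(X, **{"metric": "euclidean", "method": "complete"})

    frac_pos = {c: float(np.mean(labels.values[cl == c] == pos_label)) for c in (0, 1)}
    if orientation_override is not None:
        orientation = dict(orientation_override)
    else:
        if np.isclose(frac_pos[0], frac_pos[1]):
            raise ValueError(
                "cluster orientation tie: equal SVZ+ fractions in both clusters; "
                "pass orientation_override={'0': ..., '1': ...}"
            )
        top = max(frac_pos, key=frac_pos.get)
        orientation = {str(top): pos_label, str(1 - top): _neg}

    centroids = {}
    for c in (0, 1):
        centroids[orientation[str(c)]] = X[cl == c].mean(axis=0).tolist()
    return SignatureModel(
        signature_probes=probes,
        importance={p: float(ranked[p]) for p in probes},
        centroids=centroids,
        train_linkage=dict(TRAIN_LINKAGE),
        valid_linkage=dict(VALID_LINKAGE),
        orientation=orientation,
    )


def gene_cpg_count(sig: SignatureModel, annotation: pd.DataFrame) -> pd.Series:
    """Count signature CpGs per annotated gene (';'-separated multi-gene
    annotations increment every listed gene)."""
    counts: dict = {}
    for p in sig.signature_probes:
        genes = str(annotation.loc[p, "gene"]) if p in annotation.index else ""
        for g in filter(None, genes.split(";")):
            counts[g] = counts.get(g, 0) + 1
    return pd.Series(counts, dtype=int).sort_values(ascending=False)


def classify_svzm(
    m: MethylationMatrix, sig: SignatureModel, mode: str = "validation_clustering"
) -> pd.Series:
    """Assign each sample an SVZM label using the stored signature.

    Modes: ``train_clustering`` (Euclidean distance, complete linkage),
    ``validation_clustering`` (Chebyshev/"maximum" distance, Ward linkage) —
    both cut the dendrogram at 2 clusters and orient each cluster to the
    nearest training centroid — or ``centroid``, which assigns every sample
    directly to its nearest centroid (Euclidean, M-values).
    """
    missing = [p for p in sig.signature_probes if p not in m.probe_ids]
    if missing:
        raise KeyError(f"signature probes missing from matrix: {missing}")
    mv = m.subset_probes(sig.signature_probes).m_values()
    X = mv.values.T
    cent_labels = list(sig.centroids)
    C = np.array([sig.centroids[c] for c in cent_labels])

    if mode == "centroid":
        d = cdist(X, C)
        idx = d.argmin(axis=1)
        out = [cent_labels[i] for i in idx]
    elif mode in ("train_clustering", "validation_clustering"):
        spec = sig.train_linkage if mode == "train_clustering" else sig.valid_linkage
        cl = _cluster_cut2(X, spec["metric"], spec["linkage"])
        # orient: choose the cluster->centroid assignment minimizing the total
        # distance of cluster means to their assigned centroids
        means = np.array([X[cl == c].mean(axis=0) for c in (0, 1)])
        d = cdist(means, C)
        if d[0, 0] + d[1, 1] <= d[0, 1] + d[1, 0]:
            mapping = {0: cent_labels[0], 1: cent_labels[1]}
        else:
            mapping = {0: cent_labels[1], 1: cent_labels[0]}
        out = [mapping[c] for c in cl]
    else:
        raise ValueError(f"unknown mode '{mode}'")
    return pd.Series(out, index=m.sample_ids, name="svzm_label")


def discover_signature(
    m: MethylationMatrix,
    mri_labels,
    alpha: float = 0.001,
    k: int = 15,
    n_trees: int = 500,
    seed: int = 0,
    skip_stability: bool = False,
):
    """Full discovery pipeline: DMP testing -> stability pruning -> RF ranking
    -> top-k signature. Returns ``(SignatureModel, dmp_table, stable_probes)``."""
    dmp = differential_methylation(m, mri_labels, alpha=alpha)
    dmp_probes = list(dmp.index[dmp["is_dmp"]])
    if len(dmp_probes) < 2:
        raise ValueError(f"only {len(dmp_probes)} DMPs at alpha={alpha}; cannot build signature")
    m_dmp = m.subset_probes(dmp_probes)
    stable = dmp_probes if skip_stability else stability_subset(m_dmp, mri_labels)
    ranked = rf_rank(m.subset_probes(stable), mri_labels, n_trees=n_trees, seed=seed)
    k_eff = min(k, len(ranked))
    if k_eff < k:
        log.warning("ranking shorter than k=%d; using k=%d", k, k_eff)
    sig = select_signature(ranked, m.subset_probes(list(ranked.index)), mri_labels, k=k_eff)
    return sig, dmp, stable
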