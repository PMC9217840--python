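"""Contingency-table tests, rater agreement and multiple-testing control.

Chi-squared (Yates continuity correction on 2x2 only) and Fisher exact tests
delegate to scipy; Barnard's unconditional exact test is implemented here with
the Z-pooled score statistic and a deterministic nuisance-parameter grid.
Agreement statistics: Goodman-Kruskal lambda with bootstrap CI and ICC(2,1)
(two-way random effects, absolute agreement, single rater) from ANOVA mean
squares with an F-based confidence interval.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def _as_table(t) -> np.ndarray:
    a = np.asarray(t, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (a < 0).any() or a.sum() <= 0:
        raise ValueError("counts must be non-negative with positive total")
    return a


def chi_squared_test(t, continuity: str = "auto") -> dict:
    """Pearson chi-squared test; Yates correction applied iff the table is 2x2
    (and ``continuity`` is 'auto' or True). Returns statistic, df and p."""
    a = _as_table(t)
    if (a.sum(axis=0) == 0).any() or (a.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin")
    correct = a.shape == (2, 2) if continuity == "auto" else bool(continuity)
    stat, p, df, _ = stats.chi2_contingency(a, correction=correct)
    return {"statistic": float(stat), "df": int(df), "p": float(p)}


def fisher_exact(t) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric tail sum)."""
    a = _as_table(t)
    if a.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    return float(stats.fisher_exact(a, alternative="two-sided")[1])


def _z_pooled(x1, x2, n1: int, n2: int) -> np.ndarray:
    """Z-pooled score statistic for success counts x1/n1 vs x2/n2 (vectorized)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (p1 - p2) / np.sqrt(var), 0.0)
    return z


def barnard_test(t, grid_points: int = 1001) -> float:
    """Barnard's unconditional exact test for a 2x2 table with fixed column
    (group) totals.

    The p-value maximizes, over a grid of ``grid_points`` equally spaced
    nuisance success probabilities in (0,1), the probability of all tables
    whose |Z-pooled| statistic is at least the observed one. Invariant to
    swapping the two groups; returns a value in (0, 1].
    """
    a = _as_table(t)
    if a.shape != (2, 2):
        raise ValueError("Barnard test requires a 2x2 table")
    x1, x2 = a[0]
    n1, n2 = int(a[:, 0].sum()), int(a[:, 1].sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both group sizes must be positive")
    z_obs = abs(_z_pooled(x1, x2, n1, n2))
    if z_obs == 0:
        return 1.0
    y1 = np.arange(n1 + 1)
    y2 = np.arange(n2 + 1)
    Z = np.abs(_z_pooled(y1[:, None], y2[None, :], n1, n2))
    extreme = Z >= z_obs - 1e-12
    pis = np.linspace(0, 1, grid_points + 2)[1:-1]
    best = 0.0
    for pi in pis:
        p1 = stats.binom.pmf(y1, n1, pi)
        p2 = stats.binom.pmf(y2, n2, pi)
        prob = float(p1 @ extreme @ p2)
        if prob > best:
            best = prob
    return min(best, 1.0)


def goodman_kruskal_lambda(
    t, direction: str = "column", n_boot: int = 2000, seed: int = 0
) -> dict:
    """Goodman-Kruskal lambda: proportional reduction in error predicting the
    column variable from the row variable (``direction='column'``), with a
    percentile bootstrap CI over resampled observation pairs.

    Returns ``{"lambda": value or None, "ci95": (lo, hi) or None,
    "undefined": bool}``; undefined when the modal column category already
    captures every observation (zero baseline error).
    """
    a = _as_table(t)
    if direction == "row":
        a = a.T
    elif direction != "column":
        raise ValueError("direction must be 'row' or 'column'")

    def lam(tab):
        N = tab.sum()
        denom = N - tab.sum(axis=0).max()
        if denom == 0:
            return None
        return float((tab.max(axis=1).sum() - tab.sum(axis=0).max()) / denom)

    val = lam(a)
    if val is None:
        return {"lambda": None, "ci95": None, "undefined": True}
    # reconstruct the (row, col) pairs and resample them
    rows, cols = np.nonzero(a)
    counts = a[rows, cols].astype(int)
    pairs = np.repeat(np.arange(len(rows)), counts)
    rng = np.random.default_rng(seed)
    boots = []
    N = int(a.sum())
    for _ in range(n_boot):
        pick = rng.choice(pairs, size=N, replace=True)
        tab = np.zeros_like(a)
        idx, cnt = np.unique(pick, return_counts=True)
        tab[rows[idx], cols[idx]] = cnt
        b = lam(tab)
        if b is not None:
            boots.append(b)
    lo, hi = np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan)
    return {"lambda": val, "ci95": (float(lo), float(hi)), "undefined": False}


def icc(rater_matrix: pd.DataFrame, alpha: float = 0.05, coding: dict | None = None) -> dict:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``rater_matrix`` is samples x raters; categorical labels are converted with
    ``coding`` (default ``{"SVZ-": 0, "SVZ+": 1}``) and incomplete cases are
    dropped. Returns the point estimate with an F-based 95% CI.
    """
    df = rater_matrix.copy()
    if df.shape[1] < 2:
        raise ValueError("need at least 2 raters")
    if not np.issubdtype(np.asarray(df.values).dtype, np.number):
        coding = coding or {"SVZ-": 0, "SVZ+": 1}
        df = df.apply(lambda col: col.map(coding))
    df = df.dropna().astype(float)
    n, k = df.shape
    if n < 2:
        raise ValueError("fewer than 2 complete-case samples")
    Y = df.values
    mean_all = Y.mean()
    mean_rows = Y.mean(axis=1)
    mean_cols = Y.mean(axis=0)
    ss_rows = k * ((mean_rows - mean_all) ** 2).sum()
    ss_cols = n * ((mean_cols - mean_all) ** 2).sum()
    ss_tot = ((Y - mean_all) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    value = (msr - mse) / denom if denom != 0 else np.nan

    # McGraw & Wong F-based interval for ICC(A,1)
    try:
        a_ = k * value / (n * (1 - value))
        b_ = 1 + k * value * (n - 1) / (n * (1 - value))
        v = (a_ * msc + b_ * mse) ** 2 / (
            (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    except (ZeroDivisionError, FloatingPointError, ValueError):
        lo, hi = np.nan, np.nan
    return {"icc": float(value), "ci95": (float(lo), float(hi)), "n": n, "k": k}


def consensus_rating(rater_matrix: pd.DataFrame) -> dict:
    """Per-sample consensus: the common label iff all non-missing raters agree,
    else ``None``. Also reports the consensus fraction."""
    labels = {}
    for sid, row in rater_matrix.iterrows():
        vals = row.dropna().unique()
        if len(vals) == 0:
            log.warning("sample %r has no ratings; no consensus", sid)
            labels[sid] = None
        elif len(vals) == 1:
            labels[sid] = vals[0]
        else:
            labels[sid] = None
    frac = float(np.mean([v is not None for v in labels.values()])) if labels else 0.0
    return {"labels": labels, "consensus_fraction": frac}


def bh_fdr(p_values, q: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up control at level ``q``.

    Returns a DataFrame with ``p``, monotone ``p_adj`` and ``significant``
    flags, aligned with the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    p_adj = np.empty(m)
    p_adj[order] = np.minimum(adj, 1.0)
    # step-up significance: largest i with p_(i) <= i*q/m, all smaller called
    thresh = (np.arange(m) + 1) * q / m
    passed = p[order] <= thresh
    sig = np.zeros(m, dtype=bool)
    if passed.any():
        kmax = np.max(np.nonzero(passed)[0])
        sig[order[: kmax + 1]] = True
    idx = p_values.index if isinstance(p_values, pd.Series) else None
    return pd.DataFrame({"p": p, "p_adj": p_adj, "significant": sig}, index=idx)
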