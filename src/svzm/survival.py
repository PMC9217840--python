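"""Survival analysis: Kaplan-Meier, Cox proportional hazards, Weibull AFT.

Cox models use Efron handling of tied event times and report hazard ratios
with 95% Wald intervals plus a model-level likelihood-ratio test. The Weibull
accelerated-failure-time fit reports shape/scale and, for covariates, the
hazard-ratio transform ``HR = exp(-shape * beta_AFT)`` implied by the
Weibull PH/AFT equivalence. Multivariable fits guard against small-sample
instability (events-per-variable < 5) unless forced.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter, CoxPHFitter, WeibullAFTFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

log = logging.getLogger(__name__)

EPV_MIN = 5  # minimum events per variable for multivariable fits


@dataclass
class SurvivalFit:
    """Fitted survival regression: per-covariate coefficients with hazard
    ratios and Wald CIs, plus model-level likelihood-ratio test."""

    family: str  # "coxph" | "weibull"
    params: pd.DataFrame  # index covariate; columns coef, se, hr, ci_low, ci_high, p
    lrt_stat: float
    lrt_p: float
    loglik: float
    extra: dict = field(default_factory=dict)  # e.g. Weibull shape/scale


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    if (df["time_months"] <= 0).any():
        raise ValueError("survival times must be > 0")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return df


def km_estimate(records: pd.DataFrame, group: str | None = None) -> dict:
    """Product-limit survival estimate, optionally per group.

    Returns ``{group_value: {"survival": DataFrame, "median": float}}``
    (a single ``"all"`` entry when ``group`` is None).
    """
    df = _validate(records)
    groups = {"all": df} if group is None else dict(tuple(df.groupby(group)))
    out = {}
    for g, sub in groups.items():
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_months"], sub["event"])
        out[g] = {
            "survival": kmf.survival_function_.rename(columns={"KM_estimate": "S"}),
            "median": float(kmf.median_survival_time_),
        }
    return out


def _design(records: pd.DataFrame, covariates: list) -> pd.DataFrame:
    X = records[covariates].apply(pd.to_numeric, errors="raise")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.values]))
    if rank < len(covariates) + 1:
        # name a collinear column by greedy rank probing
        bad = []
        cols = []
        base = [np.ones(len(X))]
        for c in covariates:
            trial = np.column_stack(base + [X[c].values])
            if np.linalg.matrix_rank(trial) == len(base):
                bad.append(c)
            else:
                base.append(X[c].values)
                cols.append(c)
        raise ValueError(f"design matrix rank-deficient; collinear columns: {bad}")
    return X


def cox_fit(
    records: pd.DataFrame,
    covariates: list,
    force: bool = False,
    alpha: float = 0.05,
) -> SurvivalFit:
    """Cox PH fit (Efron ties) with LRT against the null model."""
    df = _validate(records)
    n_events = int(df["event"].sum())
    if n_events < 1:
        raise ValueError("no events observed; Cox model undefined")
    _design(df, covariates)
    if len(covariates) > 1 and n_events / len(covariates) < EPV_MIN and not force:
        raise ValueError(
            f"{n_events} events for {len(covariates)} covariates "
            f"(< {EPV_MIN} events/variable); small-n instability — pass force=True to fit"
        )
    cph = CoxPHFitter()
    data = df[["time_months", "event"] + covariates]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col="time_months", event_col="event")
    except ConvergenceError as e:
        raise RuntimeError(
            f"Cox fit did not converge (possible monotone likelihood / perfect separation): {e}"
        ) from e
    z = stats.norm.ppf(1 - alpha / 2)
    s = cph.summary
    params = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": np.exp(s["coef"]),
            "ci_low": np.exp(s["coef"] - z * s["se(coef)"]),
            "ci_high": np.exp(s["coef"] + z * s["se(coef)"]),
            "p": s["p"],
        }
    )
    lrt = cph.log_likelihood_ratio_test()
    return SurvivalFit(
        family="coxph",
        params=params,
        lrt_stat=float(lrt.test_statistic),
        lrt_p=float(lrt.p_value),
        loglik=float(cph.log_likelihood_),
    )


def weibull_fit(
    records: pd.DataFrame, covariates: list | None = None, force: bool = False
) -> SurvivalFit:
    """Weibull AFT maximum-likelihood fit with right censoring.

    ``extra`` carries the baseline ``shape`` (rho) and ``scale`` (lambda, in
    months at covariates=0). Covariate rows report the PH-equivalent hazard
    ratio ``exp(-shape * beta_AFT)``.
    """
    covariates = covariates or []
    df = _validate(records)
    if int(df["event"].sum()) < 2:
        raise ValueError("need >= 2 events for a Weibull fit")
    if covariates:
        _design(df, covariates)
        if len(covariates) > 1 and df["event"].sum() / len(covariates) < EPV_MIN and not force:
            raise ValueError("events-per-variable < 5; pass force=True to fit")
    aft = WeibullAFTFitter()
    data = df[["time_months", "event"] + covariates]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aft.fit(data, duration_col="time_months", event_col="event")
    except (ConvergenceError, np.linalg.LinAlgError) as e:
        raise RuntimeError(f"Weibull fit did not converge: {e}") from e
    shape = float(np.exp(aft.params_[("rho_", "Intercept")]))
    scale = float(np.exp(aft.params_[("lambda_", "Intercept")]))
    rows = {}
    for cov in covariates:
        coef = float(aft.params_[("lambda_", cov)])
        se = float(aft.standard_errors_[("lambda_", cov)])
        hr = float(np.exp(-shape * coef))
        # delta-method Wald CI on the HR scale (treating shape as fixed)
        lo = float(np.exp(-shape * (coef + 1.96 * se)))
        hi = float(np.exp(-shape * (coef - 1.96 * se)))
        p = float(aft.summary.loc[("lambda_", cov), "p"])
        rows[cov] = {"coef": coef, "se": se, "hr": hr, "ci_low": lo, "ci_high": hi, "p": p}
    params = pd.DataFrame(rows).T if rows else pd.DataFrame(
        columns=["coef", "se", "hr", "ci_low", "ci_high", "p"]
    )
    if covariates:
        lrt_res = aft.log_likelihood_ratio_test()
        lrt_stat, lrt_p = float(lrt_res.test_statistic), float(lrt_res.p_value)
    else:
        lrt_stat, lrt_p = 0.0, 1.0
    return SurvivalFit(
        family="weibull",
        params=params,
        lrt_stat=lrt_stat,
        lrt_p=lrt_p,
        loglik=float(aft.log_likelihood_),
        extra={"shape": shape, "scale": scale},
    )


def univariable_screen(records: pd.DataFrame, covariates: list) -> pd.DataFrame:
    """One single-covariate Cox fit per covariate; covariates with a single
    observed level are skipped with a warning. Returns an HR/CI/p table."""
    rows = []
    for cov in covariates:
        if records[cov].nunique() < 2:
            log.warning("univariable_screen: covariate %r has one level; skipped", cov)
            continue
        fit = cox_fit(records, [cov])
        r = fit.params.loc[cov]
        rows.append(
            {
                "covariate": cov,
                "hr": r["hr"],
                "ci_low": r["ci_low"],
                "ci_high": r["ci_high"],
                "p": r["p"],
                "lrt_p": fit.lrt_p,
            }
        )
    return pd.DataFrame(rows).set_index("covariate") if rows else pd.DataFrame()
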