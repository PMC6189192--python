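"""Survival analysis: Kaplan-Meier, log-rank, Cox proportional hazards.

Thin, contract-checked wrappers around lifelines. Stage enters the Cox models
as a single ordinal covariate, age as continuous, gender as a binary
indicator; ties use the Efron approximation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .containers import CoxFit
from .errors import DataError, FitError, UsageError

OUTCOME_COLUMNS = {"OS": ("os_time", "os_event"), "RFS": ("rfs_time", "rfs_event")}


def kaplan_meier(times, events) -> pd.DataFrame:
    """Product-limit survival estimate with at-risk counts.

    Returns a step-function table (one row per distinct observed time) with
    columns ``survival`` and ``at_risk``; S(0) = 1 and the estimate is
    non-increasing.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise DataError("need at least one observation")
    if (times < 0).any():
        raise DataError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"]
    out = pd.DataFrame({"survival": surv, "at_risk": at_risk.reindex(surv.index)})
    out.index.name = "time"
    return out


def logrank_test(times, events, group_labels) -> tuple[float, int, float]:
    """k-group log-rank test; returns (chi-square, df, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(group_labels)
    k = len(np.unique(groups))
    if k < 2:
        raise UsageError("log-rank test needs >= 2 groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), k - 1, float(res.p_value)


def cox_fit(clinical: pd.DataFrame, covariates: list[str], outcome: str = "OS") -> CoxFit:
    """Cox proportional-hazards fit with per-covariate Wald tests.

    ``clinical`` must carry the outcome columns (os_time/os_event or
    rfs_time/rfs_event) and the requested covariates. Collinear or constant
    covariates raise rather than producing silent output.
    """
    if outcome not in OUTCOME_COLUMNS:
        raise UsageError(f"outcome must be one of {sorted(OUTCOME_COLUMNS)}")
    tcol, ecol = OUTCOME_COLUMNS[outcome]
    missing = [c for c in [tcol, ecol, *covariates] if c not in clinical.columns]
    if missing:
        raise UsageError(f"clinical table lacks columns: {missing}")
    df = clinical[[tcol, ecol, *covariates]].dropna()
    if int(df[ecol].sum()) == 0:
        raise DataError("no events; Cox model cannot be fit")
    X = df[covariates].to_numpy(dtype=float)
    stds = X.std(axis=0)
    if (stds == 0).any():
        bad = [c for c, s in zip(covariates, stds) if s == 0]
        raise FitError(f"constant covariates: {bad}")
    if np.linalg.matrix_rank(np.column_stack([X - X.mean(axis=0)])) < len(covariates):
        raise FitError("collinear covariates; design matrix is rank deficient")
    n_events = int(df[ecol].sum())
    if n_events < len(covariates):
        import warnings

        warnings.warn("fewer events than covariates; estimates will be unstable", stacklevel=2)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=tcol, event_col=ecol)
    except Exception as exc:  # lifelines convergence errors
        raise FitError(f"Cox fit failed: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "hazard_ratio": np.exp(s["coef"]),
            "ci95_low": np.exp(s["coef lower 95%"]),
            "ci95_high": np.exp(s["coef upper 95%"]),
            "wald_p": s["p"],
        }
    )
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        n=int(len(df)),
        n_events=n_events,
    )
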