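"""Kaplan-Meier curves, log-rank tests and Cox models on the risk index.

Thin, contract-checked wrappers around lifelines, plus the backward-
elimination multivariate Cox procedure used to adjust the signature for
standard clinical covariates (age, tumor size, grade, ER status).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import CollinearityError, ConvergenceError, ValidationError
from .signature import _check_survival


def kaplan_meier(time, event, groups) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group.

    Returns, per group, a step-function table with columns ``time``,
    ``survival`` and ``at_risk``; censored subjects shrink the risk set
    without a step.
    """
    time, event = _check_survival(time, event)
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise ValidationError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        tbl = kmf.event_table
        curve = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.values,
                "survival": kmf.survival_function_["KM_estimate"].values,
            }
        )
        curve["at_risk"] = tbl["at_risk"].reindex(curve["time"]).values
        out[g] = curve
    return out


def logrank_test(time, event, groups) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its p-value."""
    time, event = _check_survival(time, event)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValidationError(f"log-rank test needs exactly 2 groups, got {len(levels)}")
    if event.sum() == 0:
        raise ValidationError("log-rank test needs at least one event")
    m = groups == levels[0]
    res = _ll_logrank(time[m], time[~m], event[m], event[~m])
    return float(res.test_statistic), float(res.p_value)


def refit_continuous_cox(indices, time, event) -> dict:
    """Univariate Cox of survival on the continuous signature index.

    On the training cohort itself this returns HR = e (~2.718) because the
    index is that model's own fitted linear predictor, so the partial
    likelihood is stationary at coefficient 1.
    """
    time, event = _check_survival(time, event)
    if event.sum() < 10:
        raise ValidationError("need >= 10 events for a stable continuous refit")
    df = pd.DataFrame({"index": np.asarray(indices, dtype=float), "time": time, "event": event})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:
        raise ConvergenceError(f"continuous Cox refit failed: {exc}") from exc
    coef = float(cph.params_["index"])
    se = float(cph.standard_errors_["index"])
    return {
        "coef": coef,
        "hr": float(np.exp(coef)),
        "ci_lower": float(np.exp(coef - 1.959963984540054 * se)),
        "ci_upper": float(np.exp(coef + 1.959963984540054 * se)),
        "p": float(cph.summary.loc["index", "p"]),
    }


def _check_collinearity(df: pd.DataFrame):
    cols = df.columns
    corr = np.corrcoef(df.values.T)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if abs(corr[i, j]) > 0.9999:
                raise CollinearityError(
                    f"covariates {cols[i]!r} and {cols[j]!r} are collinear"
                )


def multivariate_cox_backward(
    covariates: pd.DataFrame, time, event, alpha_remove: float = 0.05, eliminate: bool = True
) -> pd.DataFrame:
    """Multivariate Cox with Wald-test backward elimination.

    Starting from the full model, the covariate with the largest Wald p-value
    above ``alpha_remove`` is dropped and the model refitted, until every
    retained covariate passes.  ``eliminate=False`` reports the full adjusted
    model without dropping anything.  Returns a table with hazard ratio, 95%
    CI and p per retained covariate.
    """
    time, event = _check_survival(time, event)
    if event.sum() < 10:
        raise ValidationError("need >= 10 events for the multivariate model")
    cov = covariates.astype(float).reset_index(drop=True)
    if cov.isna().any().any():
        raise ValidationError("covariates contain missing values; complete cases only")
    _check_collinearity(cov)
    remaining = list(cov.columns)
    while True:
        df = cov[remaining].copy()
        df["time"] = time
        df["event"] = event
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except Exception as exc:
            raise ConvergenceError(f"multivariate Cox fit failed: {exc}") from exc
        pvals = cph.summary.loc[remaining, "p"]
        if not eliminate or len(remaining) == 1:
            break
        worst = pvals.idxmax()
        if pvals[worst] <= alpha_remove:
            break
        remaining.remove(worst)
    summary = cph.summary.loc[remaining]
    return pd.DataFrame(
        {
            "hr": np.exp(summary["coef"]),
            "ci_lower": np.exp(summary["coef lower 95%"]),
            "ci_upper": np.exp(summary["coef upper 95%"]),
            "p": summary["p"],
        }
    )
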