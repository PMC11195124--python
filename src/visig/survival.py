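"""Time-to-event association of scores and labels.

Thin contract layer over lifelines: univariate/multivariable Cox
proportional-hazards regression (Efron tie handling) reporting hazard ratios
with Wald confidence intervals, and Kaplan–Meier curves with the standard
log-rank test, optionally administratively censored at a follow-up horizon.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = ["cox_ph", "km_logrank", "apply_horizon"]


def _validate_surv(surv: pd.DataFrame) -> None:
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    if surv["event"].sum() == 0:
        raise ValueError("no events observed")


def apply_horizon(surv: pd.DataFrame, horizon: Optional[float]) -> pd.DataFrame:
    """Administrative censoring at a follow-up horizon (months)."""
    if horizon is None:
        return surv.copy()
    out = surv.copy()
    over = out["time"] > horizon
    out.loc[over, "time"] = horizon
    out.loc[over, "event"] = 0
    return out


def cox_ph(surv: pd.DataFrame, covariates: pd.DataFrame,
           horizon: Optional[float] = None) -> pd.DataFrame:
    """Cox proportional-hazards fit; one row per covariate.

    ``surv`` has columns ``time`` and ``event``; ``covariates`` is indexed
    like ``surv``.  Returns HR = exp(beta) with the Wald 95% CI and p-value.
    Constant covariates are an error, as is a dataset with no events.
    """
    covariates = covariates.reindex(surv.index)
    for col in covariates.columns:
        values = covariates[col].to_numpy(float)
        if not np.isfinite(values).all():
            raise ValueError(f"covariate {col!r} has non-finite values")
        if np.ptp(values) == 0:
            raise ValueError(f"covariate {col!r} is constant")
    data = apply_horizon(surv, horizon)
    _validate_surv(data)
    frame = pd.concat([data[["time", "event"]], covariates], axis=1)
    fitter = CoxPHFitter()
    fitter.fit(frame, duration_col="time", event_col="event")
    summary = fitter.summary
    return pd.DataFrame({
        "coef": summary["coef"],
        "hr": summary["exp(coef)"],
        "hr_ci_low": summary["exp(coef) lower 95%"],
        "hr_ci_high": summary["exp(coef) upper 95%"],
        "pvalue": summary["p"],
    })


def km_logrank(surv: pd.DataFrame, groups: pd.Series,
               horizon: Optional[float] = None):
    """Kaplan–Meier curves per group and the log-rank test between them.

    Returns ``(curves, p)`` where ``curves`` maps group label to a survival
    curve table (columns ``time`` and ``survival``).
    """
    groups = groups.reindex(surv.index)
    if groups.nunique() < 2:
        raise ValueError("need at least two groups")
    data = apply_horizon(surv, horizon)
    _validate_surv(data)

    curves = {}
    for label, idx in groups.groupby(groups).groups.items():
        km = KaplanMeierFitter()
        km.fit(data.loc[idx, "time"], data.loc[idx, "event"])
        curve = km.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        curves[label] = curve
    test = multivariate_logrank_test(data["time"], groups, data["event"])
    return curves, float(test.p_value)
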