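"""Survival analysis: Cox proportional hazards on cell-type-group scores,
risk stratification by linear-predictor quantile, Kaplan-Meier estimation
and the log-rank test.

Model fitting is delegated to lifelines (Efron tie handling, Newton
iterations driven to tight convergence); this module owns input contracts,
the stratification rule (strictly-above-quantile goes to high risk, ties at
the threshold to low) and tabular outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _lifelines_logrank

from .io import logger


@dataclass
class CoxResult:
    coefficients: pd.Series
    standard_errors: pd.Series
    linear_predictors: pd.Series   # centered at covariate means
    n_events: int


@dataclass
class RiskStratification:
    linear_predictors: pd.Series
    labels: pd.Series              # "high" / "low"
    risk_quantile: float
    threshold: float
    covariates: list[str]
    coefficients: pd.Series
    standard_errors: pd.Series


def _align(features: pd.DataFrame, survival: pd.DataFrame) -> pd.DataFrame:
    missing = sorted(set(features.index) - set(survival.index))
    if missing:
        raise KeyError(f"survival table missing samples: {missing[:10]}")
    df = features.copy()
    df["time_days"] = survival.loc[features.index, "time_days"]
    df["event"] = survival.loc[features.index, "event"]
    return df


def fit_cox(features: pd.DataFrame, survival: pd.DataFrame) -> CoxResult:
    """Cox PH fit (partial likelihood, Efron ties) of survival on covariates.

    The linear predictor is beta . (x - x̄), i.e. centered at covariate
    means. Supports univariate and multivariate models.
    """
    if features.shape[0] <= features.shape[1]:
        raise ValueError("need more samples than covariates")
    sd = features.std(axis=0, ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant covariates: {constant}")
    df = _align(features, survival)
    n_events = int(df["event"].sum())
    if n_events < 2:
        raise ValueError(f"need >= 2 events to fit a Cox model (got {n_events})")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time_days", event_col="event",
                fit_options={"precision": 1e-12, "r_precision": 1e-18, "max_steps": 500})
    except ConvergenceError as exc:
        raise ValueError(
            f"Cox model did not converge (possible separation) for covariates "
            f"{list(features.columns)}: {exc}") from exc
    lp = cph.predict_log_partial_hazard(df)
    return CoxResult(
        coefficients=cph.params_.rename("coef"),
        standard_errors=cph.standard_errors_.rename("se"),
        linear_predictors=pd.Series(np.asarray(lp, dtype=float).ravel(),
                                    index=features.index, name="linear_predictor"),
        n_events=n_events,
    )


def stratify(linear_predictors: pd.Series, risk_quantile: float = 0.5,
             cox: CoxResult | None = None) -> RiskStratification:
    """High/low risk split at the given linear-predictor quantile.

    "High" means strictly above the quantile; ties at the threshold go to
    low, so a degenerate all-equal predictor yields all-low with a warning.
    At quantile 0.5 this is the median split; 0.66 marks the top 34% high.
    """
    lp = linear_predictors.astype(float)
    if not np.isfinite(lp.values).all():
        raise ValueError("linear predictors must be finite")
    thr = float(np.quantile(lp.values, risk_quantile))
    high = lp > thr
    if not high.any():
        logger.warning("no sample strictly above the %.2f quantile; all labeled low risk",
                       risk_quantile)
    labels = pd.Series(np.where(high, "high", "low"), index=lp.index, name="risk")
    return RiskStratification(
        linear_predictors=lp, labels=labels, risk_quantile=risk_quantile,
        threshold=thr,
        covariates=list(cox.coefficients.index) if cox else [],
        coefficients=cox.coefficients if cox else pd.Series(dtype=float),
        standard_errors=cox.standard_errors if cox else pd.Series(dtype=float),
    )


def km_estimate(survival: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival curve: columns time, survival, at_risk, censored."""
    if survival.shape[0] < 1:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(survival["time_days"], survival["event"])
    table = kmf.event_table
    out = pd.DataFrame({
        "time": kmf.survival_function_.index.values,
        "survival": kmf.survival_function_.iloc[:, 0].values,
        "at_risk": table["at_risk"].reindex(kmf.survival_function_.index).values,
        "censored": table["censored"].reindex(kmf.survival_function_.index).values,
    })
    return out.reset_index(drop=True)


def logrank(labels: pd.Series, survival: pd.DataFrame) -> tuple[float, float]:
    """Mantel-Haenszel log-rank test between two groups.

    Returns (chi-square statistic on 1 df, p-value).
    """
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(groups)}")
    surv = survival.loc[labels.index]
    a = labels == groups[0]
    if a.all() or (~a).all():
        raise ValueError("both groups must be non-empty")
    res = _lifelines_logrank(
        surv.loc[a.values, "time_days"], surv.loc[(~a).values, "time_days"],
        surv.loc[a.values, "event"], surv.loc[(~a).values, "event"],
    )
    return float(res.test_statistic), float(res.p_value)
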