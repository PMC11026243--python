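"""Weighted discrete-time outcome models, summary hazard ratios, survival
curves and person-time summaries.

The outcome model is a weighted pooled logistic regression of the monthly
event indicator on regimen indicators (never-initiate as reference) plus
time terms; the variance is a robust sandwich clustered on the original
patient, so the clones of one patient share a cluster.  With rare monthly
events the exponentiated regimen coefficient is read as a hazard ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import FittingError, InputError

REFERENCE_LABEL = "never"


def incidence_rate(events: int, person_years: float) -> float:
    """Events per 1000 person-years, rounded half-up to 2 decimals."""
    if person_years <= 0:
        raise InputError(f"person_years must be positive, got {person_years}")
    if events < 0:
        raise InputError(f"events must be non-negative, got {events}")
    rate = Decimal(events) / Decimal(str(person_years)) * Decimal(1000)
    return float(rate.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def risk_rows(clones: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Clone-months at risk for the first event of ``outcome``.

    Drops artificially censored rows, then truncates each clone at its first
    event (the event row itself stays in the risk set).
    """
    col = f"event_{outcome}"
    if col not in clones.columns:
        raise InputError(f"unknown outcome {outcome!r}")
    out = clones[~clones["artificially_censored"].astype(bool)].copy()
    out = out.sort_values(["patient_id", "regimen", "month"], kind="mergesort")
    ev = out[col].astype(int)
    cum = out.groupby(["patient_id", "regimen"], sort=False)[col].cumsum()
    prior = (cum - ev) > 0
    return out[~prior.to_numpy()].reset_index(drop=True)


def person_time_summary(clones: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Per-regimen events, person-years and incidence rate per 1000 py.

    Each at-risk clone-month contributes 1/12 person-year; a clone's first
    event is counted once, at its event month.
    """
    rows = risk_rows(clones, outcome)
    col = f"event_{outcome}"
    recs = []
    for label, grp in rows.groupby("regimen"):
        events = int(grp[col].sum())
        py = len(grp) / 12.0
        recs.append({
            "regimen": label,
            "events": events,
            "person_years": py,
            "incidence_rate_per_1000py": incidence_rate(events, py) if py > 0 else float("nan"),
        })
    return pd.DataFrame(recs)


@dataclass
class OutcomeFit:
    """A fitted weighted discrete-time hazard model for one outcome."""

    outcome: str
    result: object
    regimen_labels: list       # non-reference labels, design order
    design_columns: list
    time: str
    zero_event_arms: list      # arms with no events; HRs there are unreliable


def _outcome_design(rows: pd.DataFrame, labels: list, time: str,
                    columns: list | None = None) -> pd.DataFrame:
    X = pd.DataFrame(index=rows.index)
    X["const"] = 1.0
    for lab in labels:
        X[f"regimen_{lab}"] = (rows["regimen"] == lab).astype(float)
    if time == "quadratic":
        X["month"] = rows["month"].astype(float)
        X["month_sq"] = X["month"] ** 2
    else:
        for m in sorted(rows["month"].unique()):
            if m == 0:
                continue
            X[f"month_{m}"] = (rows["month"] == m).astype(float)
    if columns is not None:
        for c in columns:
            if c not in X:
                X[c] = 0.0
        X = X[columns]
    return X


def fit_outcome_model(clones: pd.DataFrame, outcome: str,
                      weight_col: str | None = "truncated_weight",
                      time: str = "quadratic") -> OutcomeFit:
    """Weighted pooled logistic hazard model with cluster-robust variance.

    ``weight_col=None`` fits the unweighted (but cloned and censored) model,
    the analogue of an unadjusted comparison.  Arms without a single event
    are flagged in ``zero_event_arms``; their coefficients are unreliable
    but the remaining arms are still estimated.
    """
    rows = risk_rows(clones, outcome)
    if len(rows) == 0:
        raise FittingError(f"no at-risk clone-months for outcome {outcome!r}")
    col = f"event_{outcome}"
    labels = [lab for lab in rows["regimen"].unique() if lab != REFERENCE_LABEL]
    labels = sorted(labels)
    ev_by_arm = rows.groupby("regimen")[col].sum()
    zero_arms = [lab for lab, n in ev_by_arm.items() if n == 0]
    X = _outcome_design(rows, labels, time)
    w = np.ones(len(rows)) if weight_col is None else rows[weight_col].to_numpy(float)
    groups = rows["patient_id"].to_numpy()
    try:
        with warnings.catch_warnings():
            warnings.filterwarnings(
                "ignore", message="cov_type not fully supported with var_weights")
            res = sm.GLM(rows[col].astype(float), X,
                         family=sm.families.Binomial(), var_weights=w).fit(
                cov_type="cluster", cov_kwds={"groups": groups})
    except Exception as exc:
        raise FittingError(f"outcome model for {outcome!r} failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise FittingError(f"outcome model for {outcome!r} did not converge")
    return OutcomeFit(outcome=outcome, result=res, regimen_labels=labels,
                      design_columns=list(X.columns), time=time,
                      zero_event_arms=zero_arms)


def summary_hr(fit: OutcomeFit, alpha: float = 0.05) -> pd.DataFrame:
    """Per-regimen hazard ratios with robust Wald confidence intervals."""
    z = stats.norm.ppf(1 - alpha / 2)
    recs = []
    for lab in fit.regimen_labels:
        name = f"regimen_{lab}"
        coef = float(fit.result.params[name])
        se = float(fit.result.bse[name])
        recs.append({
            "regimen": lab,
            "hr": float(np.exp(coef)),
            "ci_lower": float(np.exp(coef - z * se)),
            "ci_upper": float(np.exp(coef + z * se)),
            "log_hr": coef,
            "se_log_hr": se,
            "zero_events": lab in fit.zero_event_arms,
        })
    return pd.DataFrame(recs)


def survival_curves(fit: OutcomeFit, clones: pd.DataFrame,
                    weight_col: str | None = "truncated_weight") -> pd.DataFrame:
    """Standardized per-regimen survival curves.

    For each regimen and month, the fitted monthly hazard is averaged over
    that regimen's at-risk clone-months with weights, and
    S(t) = prod_{s<t} (1 - hbar(s)), S(0) = 1.
    """
    rows = risk_rows(clones, fit.outcome)
    all_labels = fit.regimen_labels + [REFERENCE_LABEL]
    X = _outcome_design(rows, fit.regimen_labels, fit.time,
                        columns=fit.design_columns)
    h_hat = np.asarray(fit.result.predict(X))
    w = np.ones(len(rows)) if weight_col is None else rows[weight_col].to_numpy(float)
    recs = []
    for lab in all_labels:
        mask = (rows["regimen"] == lab).to_numpy()
        if not mask.any():
            continue
        sub = pd.DataFrame({"month": rows.loc[mask, "month"].to_numpy(),
                            "h": h_hat[mask], "w": w[mask]})
        hbar = sub.groupby("month").apply(
            lambda g: np.average(g["h"], weights=g["w"]), include_groups=False)
        months = np.arange(int(hbar.index.max()) + 1)
        hvec = hbar.reindex(months, fill_value=0.0).to_numpy()
        surv = np.concatenate([[1.0], np.cumprod(1.0 - hvec)])
        for t, s in enumerate(surv):
            recs.append({"regimen": lab, "month": t, "survival": float(s)})
    return pd.DataFrame(recs)
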