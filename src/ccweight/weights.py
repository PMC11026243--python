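"""Discrete-time initiation / dropout models and cumulative inverse-probability
weights.

Both probability models are pooled logistic regressions fitted on the
original (uncloned) panel; predictions are then applied to the clone rows.
Weights are unstabilized: every per-month factor is the reciprocal of a
conditional probability, hence >= 1, and the cumulative weight is a running
product that can only grow.  Extreme weights are controlled by percentile
truncation over the pooled clone-month weight distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cloning import Regimen
from .errors import (ConfigError, FittingError, PositivityError,
                     PositivityWarning)

_EPS = 1e-12


@dataclass(frozen=True)
class CovariateSpec:
    """Columns entering the weight models, plus the time functional form."""

    baseline: tuple = ("female",)
    time_varying: tuple = ("chads_vasc",)
    time: str = "quadratic"  # "quadratic" -> month + month^2; "indicators"

    def __post_init__(self):
        if self.time not in ("quadratic", "indicators"):
            raise ConfigError(f"time must be 'quadratic' or 'indicators', got {self.time!r}")


@dataclass
class WeightModel:
    """Fitted initiation and dropout components plus their design columns."""

    spec: CovariateSpec
    initiation_result: object
    initiation_columns: list
    dropout_result: object | None  # None => no-dropout guard, factors all 1
    dropout_columns: list | None


def _design(df: pd.DataFrame, spec: CovariateSpec, extra: tuple = (),
            columns: list | None = None) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    for col in tuple(spec.baseline) + tuple(spec.time_varying) + tuple(extra):
        X[col] = df[col].astype(float)
    if spec.time == "quadratic":
        X["month"] = df["month"].astype(float)
        X["month_sq"] = X["month"] ** 2
    else:
        for m in sorted(df["month"].unique()):
            if m == 0:
                continue
            X[f"month_{m}"] = (df["month"] == m).astype(float)
    if columns is not None:  # align prediction design with the fit design
        for c in columns:
            if c not in X:
                X[c] = 0.0
        X = X[columns]
    return X


def _fit_pooled_logit(endog, exog, what: str, warn_low: bool = True):
    if endog.sum() == 0:
        raise FittingError(f"cannot fit {what} model: no events in risk set")
    try:
        res = sm.GLM(endog.astype(float), exog,
                     family=sm.families.Binomial()).fit()
    except Exception as exc:  # separation, singular design, ...
        raise FittingError(f"{what} model failed to fit: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise FittingError(f"{what} model did not converge (non-finite coefficients)")
    p = np.asarray(res.fittedvalues)
    bad = p >= 1 - 1e-10
    if warn_low:  # near-zero only matters when 1/p enters a weight
        bad = bad | (p <= 1e-10)
    if bad.any():
        warnings.warn(
            f"{what} model predicts probabilities at the 0/1 boundary for "
            f"{int(bad.sum())} rows",
            PositivityWarning, stacklevel=3)
    return res


def initiation_risk_set(panel: pd.DataFrame) -> pd.DataFrame:
    """Person-months where initiation could still happen (not yet treated at
    the month's decision point)."""
    return panel[~panel["on_oac"].astype(bool)
                 | panel["initiated_this_month"].astype(bool)]


def fit_initiation_model(panel: pd.DataFrame, spec: CovariateSpec):
    """Pooled logistic for P(initiate this month | covariates, month)."""
    risk = initiation_risk_set(panel)
    X = _design(risk, spec)
    res = _fit_pooled_logit(risk["initiated_this_month"].astype(float), X, "initiation")
    return res, list(X.columns)


def fit_dropout_model(panel: pd.DataFrame, spec: CovariateSpec):
    """Pooled logistic for P(dropout this month | covariates, treatment, month).

    Returns (None, None) when the panel has no dropout at all — the no-event
    guard; all censoring factors then equal 1.
    """
    if panel["dropout"].sum() == 0:
        warnings.warn("no dropout events in panel; censoring factors set to 1",
                      UserWarning, stacklevel=2)
        return None, None
    X = _design(panel, spec, extra=("on_oac",))
    res = _fit_pooled_logit(panel["dropout"].astype(float), X, "dropout",
                            warn_low=False)
    return res, list(X.columns)


def fit_weight_models(panel: pd.DataFrame,
                      spec: CovariateSpec | None = None) -> WeightModel:
    spec = spec or CovariateSpec()
    init_res, init_cols = fit_initiation_model(panel, spec)
    drop_res, drop_cols = fit_dropout_model(panel, spec)
    return WeightModel(spec=spec, initiation_result=init_res,
                       initiation_columns=init_cols,
                       dropout_result=drop_res, dropout_columns=drop_cols)


def _predict(result, columns, df, spec, extra=()):
    X = _design(df, spec, extra=extra, columns=columns)
    return np.asarray(result.predict(X))


def compute_cumulative_weights(clones: pd.DataFrame, model: WeightModel,
                               regimens: list[Regimen],
                               grace_months: int = 1) -> pd.DataFrame:
    """Per clone-month treatment and censoring factors and their running
    product.

    Treatment factor for a threshold-k clone: 1/(1-p) while the score has
    not yet reached k (remaining untreated is required); 1 during the grace
    window after crossing (either behaviour complies); 1/p at the deadline
    month when initiation is required and happens; 1 after initiation.  For
    a never clone: 1/(1-p) while untreated.  Censoring factor: 1/(1-d) for
    every month remaining under observation.  Factors on artificially
    censored rows are left at 1 (those rows never enter a risk set).
    """
    out = clones.copy()
    n = len(out)
    if n == 0:
        for c in ("factor_treatment", "factor_censoring", "cumulative_weight"):
            out[c] = pd.Series([], dtype=float)
        return out

    thresholds = {r.label: r.k for r in regimens if r.kind == "threshold"}
    never_labels = {r.label for r in regimens if r.kind == "never"}

    p_init = _predict(model.initiation_result, model.initiation_columns,
                      out, model.spec)
    factor_t = np.ones(n)
    on = out["on_oac"].to_numpy(dtype=bool)
    init_now = out["initiated_this_month"].to_numpy(dtype=bool)
    censored = out["artificially_censored"].to_numpy(dtype=bool)
    month = out["month"].to_numpy()

    # first crossing month per (patient, regimen) for threshold arms
    k_of = out["regimen"].map(thresholds)
    crossed = out["chads_vasc"].to_numpy() >= k_of.fillna(99).to_numpy()
    out["_cross_month"] = np.where(crossed, month, np.inf)
    t0 = out.groupby(["patient_id", "regimen"], sort=False)["_cross_month"].transform("min").to_numpy()
    out = out.drop(columns="_cross_month")

    is_thresh = k_of.notna().to_numpy()
    is_never = out["regimen"].isin(never_labels).to_numpy()

    need_untreated = (~on & ~censored) & (is_never | (is_thresh & (month < t0)))
    if np.any(p_init[need_untreated] >= 1 - _EPS):
        raise PositivityError("predicted initiation probability of 1 in a month "
                              "requiring no initiation")
    factor_t[need_untreated] = 1.0 / (1.0 - p_init[need_untreated])

    deadline = t0 + grace_months
    need_initiate = is_thresh & ~censored & init_now & (month == deadline)
    if np.any(p_init[need_initiate] <= _EPS):
        raise PositivityError("predicted initiation probability of 0 in a month "
                              "requiring initiation")
    factor_t[need_initiate] = 1.0 / p_init[need_initiate]

    factor_c = np.ones(n)
    if model.dropout_result is not None:
        d_hat = _predict(model.dropout_result, model.dropout_columns,
                         out, model.spec, extra=("on_oac",))
        if np.any(d_hat[~censored] >= 1 - _EPS):
            raise PositivityError("predicted dropout probability of 1")
        factor_c[~censored] = 1.0 / (1.0 - d_hat[~censored])

    out["factor_treatment"] = factor_t
    out["factor_censoring"] = factor_c
    out = out.sort_values(["patient_id", "regimen", "month"], kind="mergesort")
    out["_per_month"] = out["factor_treatment"] * out["factor_censoring"]
    out["cumulative_weight"] = out.groupby(
        ["patient_id", "regimen"], sort=False)["_per_month"].cumprod()
    out = out.drop(columns="_per_month")
    return out.reset_index(drop=True)


def truncate_weights(clones: pd.DataFrame, percentile: float = 99.0,
                     weight_col: str = "cumulative_weight") -> pd.DataFrame:
    """Cap weights at the given pooled percentile (linear interpolation).

    The cap is computed over at-risk clone-months of all arms pooled;
    percentile 100 is the identity.
    """
    if not 0 < percentile <= 100:
        raise ConfigError(f"truncation percentile must be in (0, 100], got {percentile}")
    out = clones.copy()
    at_risk = ~out["artificially_censored"].astype(bool)
    if at_risk.sum() == 0:
        out["truncated_weight"] = out[weight_col]
        return out
    cap = float(np.percentile(out.loc[at_risk, weight_col], percentile))
    out["truncated_weight"] = np.minimum(out[weight_col], cap)
    return out


def weight_diagnostics(clones: pd.DataFrame,
                       weight_col: str = "truncated_weight") -> pd.DataFrame:
    """Per-arm weight summary (mean/SD/percentiles) over at-risk rows."""
    at_risk = clones[~clones["artificially_censored"].astype(bool)]
    rows = []
    for label, grp in at_risk.groupby("regimen"):
        w = grp[weight_col]
        rows.append({
            "regimen": label, "n_clone_months": len(w),
            "mean": w.mean(), "sd": w.std(),
            "p50": w.quantile(0.5), "p90": w.quantile(0.9),
            "p99": w.quantile(0.99), "max": w.max(),
        })
    return pd.DataFrame(rows)
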