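"""Confounded synthetic claims-style cohort generator.

Produces a long person-month panel for an elderly AFib+cancer cohort:
stroke-risk score components only turn on over time (the score is
non-decreasing), treatment initiation each month is a logistic function of
the current score (confounding by indication), and stroke/bleeding hazards
are multiplicative in the score and in treatment.  Treatment is absorbing.

Within-month order of operations (fixed, documented):
  1. covariate / score update (component onset draws, annual age increment)
  2. initiation decision (skipped when already treated)
  3. outcome, death and dropout draws (treatment affects same-month hazards)

A single numpy Generator seeded from the config drives all draws, in the
order: baseline covariates, then per-month blocks in the order above, so the
same seed and config give a bit-identical panel.

`counterfactual_truth` replays the same generative model with treatment
FORCED to follow a regimen, yielding the true cumulative incidence and
marginal hazard ratio against never-initiation — the validation oracle for
the whole estimator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .cloning import Regimen
from .errors import ConfigError, InputError
from .scores import chads_vasc, has_bled

_DEFAULT_PREVALENCES = {
    "chf": 0.15,
    "hypertension": 0.60,
    "diabetes": 0.25,
    "prior_stroke_tia": 0.10,
    "vascular_disease": 0.20,
    "renal_abnormal": 0.10,
    "liver_abnormal": 0.04,
    "bleeding_history": 0.08,
    "drugs_alcohol": 0.05,
    "active_cancer": 0.55,
    "thrombocytopenia": 0.05,
    "prior_oac": 0.10,
    "valvular_disease": 0.05,
    "recent_stroke_14d": 0.01,
    "recent_surgery_bleed_30d": 0.02,
    "esrd": 0.02,
    "continuous_enrollment": 0.97,
}

#: Fixed output column order of the person-month CSV.
PANEL_COLUMNS = [
    "patient_id", "month", "age", "female",
    "chf", "hypertension", "diabetes", "prior_stroke_tia", "vascular_disease",
    "renal_abnormal", "liver_abnormal", "bleeding_history", "drugs_alcohol",
    "cancer_type", "cancer_stage", "active_cancer", "thrombocytopenia",
    "prior_oac", "valvular_disease", "recent_stroke_14d",
    "recent_surgery_bleed_30d", "esrd", "continuous_enrollment",
    "comorbidity_score", "chads_vasc", "has_bled",
    "on_oac", "initiated_this_month",
    "event_stroke", "event_bleed", "death", "dropout", "eligible",
]

_PROGRESSING_FLAGS = ["chf", "hypertension", "diabetes", "prior_stroke_tia",
                      "vascular_disease"]


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generative model.  Every probability lives in [0,1],
    every hazard ratio is positive; violations raise ConfigError naming the
    field."""

    n_patients: int = 1000
    seed: int = 0
    max_months: int = 12
    baseline_prevalences: dict = field(default_factory=dict)
    cancer_type_probs: dict = field(
        default_factory=lambda: {"breast": 0.4, "lung": 0.25, "prostate": 0.35})
    cancer_stage_probs: dict = field(
        default_factory=lambda: {"in_situ": 0.15, "local": 0.45,
                                 "regional": 0.25, "distant": 0.15})
    age_mean: float = 76.0
    age_sd: float = 7.0
    age_min: float = 66.0
    female_fraction: float = 0.5
    score_progression_rate: float = 0.02
    init_intercept: float = -2.5
    init_score_logodds: float = 0.30
    hazard_stroke: float = 0.010
    hazard_bleed: float = 0.004
    hazard_death: float = 0.005
    hazard_dropout: float = 0.005
    oac_stroke_hr: float = 0.6
    oac_bleed_hr: float = 1.5
    score_stroke_hr: float = 1.20
    score_bleed_hr: float = 1.08

    def __post_init__(self):
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")
        if self.max_months < 1:
            raise ConfigError("max_months must be >= 1")
        prev = dict(_DEFAULT_PREVALENCES)
        prev.update(self.baseline_prevalences)
        unknown = set(prev) - set(_DEFAULT_PREVALENCES)
        if unknown:
            raise ConfigError(f"unknown baseline_prevalences keys: {sorted(unknown)}")
        for name, p in prev.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"baseline_prevalences[{name!r}] must be in [0,1], got {p}")
        object.__setattr__(self, "baseline_prevalences", prev)
        for name in ("female_fraction", "score_progression_rate",
                     "hazard_stroke", "hazard_bleed", "hazard_death",
                     "hazard_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        for name in ("oac_stroke_hr", "oac_bleed_hr", "score_stroke_hr",
                     "score_bleed_hr"):
            v = getattr(self, name)
            if not v > 0:
                raise ConfigError(f"{name} must be > 0, got {v}")
        for dist, total in (("cancer_type_probs", self.cancer_type_probs),
                            ("cancer_stage_probs", self.cancer_stage_probs)):
            if abs(sum(total.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{dist} must sum to 1")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


def _draw_baseline(config: SimConfig, n: int, rng: np.random.Generator) -> dict:
    prev = config.baseline_prevalences
    base = {}
    # truncated-normal ages, floored to integer years, never below age_min
    raw = rng.normal(config.age_mean, config.age_sd, size=n)
    while True:
        bad = raw < config.age_min
        if not bad.any():
            break
        raw[bad] = rng.normal(config.age_mean, config.age_sd, size=int(bad.sum()))
    base["age0"] = np.floor(raw).astype(int)
    base["female"] = rng.random(n) < config.female_fraction
    for name in _DEFAULT_PREVALENCES:
        base[name] = rng.random(n) < prev[name]
    types = list(config.cancer_type_probs)
    base["cancer_type"] = np.array(types)[
        rng.choice(len(types), size=n, p=list(config.cancer_type_probs.values()))]
    stages = list(config.cancer_stage_probs)
    base["cancer_stage"] = np.array(stages)[
        rng.choice(len(stages), size=n, p=list(config.cancer_stage_probs.values()))]
    base["comorbidity_score"] = rng.poisson(1.5, size=n)
    return base


def _simulate(config: SimConfig, n: int, rng: np.random.Generator,
              forced: Regimen | None = None) -> pd.DataFrame:
    """Core generator.  ``forced=None`` gives observational (confounded)
    initiation; a Regimen forces initiation the first month the score
    reaches its threshold (or never)."""
    if n == 0:
        return pd.DataFrame({c: pd.Series([], dtype=object) for c in PANEL_COLUMNS})

    base = _draw_baseline(config, n, rng)
    flags = {name: base[name].copy() for name in _PROGRESSING_FLAGS}
    active = np.ones(n, dtype=bool)
    on_oac = np.zeros(n, dtype=bool)
    rows = []

    for m in range(config.max_months):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        # 1. covariate / score update
        for name in _PROGRESSING_FLAGS:
            off = active & ~flags[name]
            onset = rng.random(n) < config.score_progression_rate
            flags[name] = flags[name] | (off & onset)
        age = base["age0"] + m // 12
        score = chads_vasc(age, base["female"], flags["chf"],
                           flags["hypertension"], flags["diabetes"],
                           flags["prior_stroke_tia"], flags["vascular_disease"])
        bled = has_bled(age, flags["hypertension"], base["renal_abnormal"],
                        base["liver_abnormal"], flags["prior_stroke_tia"],
                        base["bleeding_history"], base["drugs_alcohol"])
        # 2. initiation decision (draw consumed every month for RNG alignment)
        u_init = rng.random(n)
        if forced is None:
            p_init = expit(config.init_intercept
                           + config.init_score_logodds * score)
            initiated = active & ~on_oac & (u_init < p_init)
        elif forced.kind == "never":
            initiated = np.zeros(n, dtype=bool)
        else:
            initiated = active & ~on_oac & (score >= forced.k)
        on_oac = on_oac | initiated
        # 3. outcome / death / dropout draws
        p_stroke = np.clip(config.hazard_stroke
                           * config.score_stroke_hr ** score
                           * np.where(on_oac, config.oac_stroke_hr, 1.0),
                           0.0, 0.99)
        p_bleed = np.clip(config.hazard_bleed
                          * config.score_bleed_hr ** score
                          * np.where(on_oac, config.oac_bleed_hr, 1.0),
                          0.0, 0.99)
        stroke = rng.random(n) < p_stroke
        bleed = rng.random(n) < p_bleed
        death = rng.random(n) < config.hazard_death
        dropout = rng.random(n) < config.hazard_dropout
        dropout = dropout & ~death  # death takes precedence within a month

        rows.append(pd.DataFrame({
            "patient_id": idx,
            "month": m,
            "age": age[idx],
            "female": base["female"][idx],
            **{name: flags[name][idx] for name in _PROGRESSING_FLAGS},
            "renal_abnormal": base["renal_abnormal"][idx],
            "liver_abnormal": base["liver_abnormal"][idx],
            "bleeding_history": base["bleeding_history"][idx],
            "drugs_alcohol": base["drugs_alcohol"][idx],
            "cancer_type": base["cancer_type"][idx],
            "cancer_stage": base["cancer_stage"][idx],
            "active_cancer": base["active_cancer"][idx],
            "thrombocytopenia": base["thrombocytopenia"][idx],
            "prior_oac": base["prior_oac"][idx],
            "valvular_disease": base["valvular_disease"][idx],
            "recent_stroke_14d": base["recent_stroke_14d"][idx],
            "recent_surgery_bleed_30d": base["recent_surgery_bleed_30d"][idx],
            "esrd": base["esrd"][idx],
            "continuous_enrollment": base["continuous_enrollment"][idx],
            "comorbidity_score": base["comorbidity_score"][idx],
            "chads_vasc": score[idx],
            "has_bled": bled[idx],
            "on_oac": on_oac[idx],
            "initiated_this_month": initiated[idx],
            "event_stroke": stroke[idx],
            "event_bleed": bleed[idx],
            "death": death[idx],
            "dropout": dropout[idx],
            "eligible": True,
        }))
        active = active & ~death & ~dropout

    panel = pd.concat(rows, ignore_index=True)
    panel = panel.sort_values(["patient_id", "month"], kind="mergesort")
    return panel.reset_index(drop=True)[PANEL_COLUMNS]


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate an observational person-month panel (confounded initiation)."""
    rng = np.random.default_rng(config.seed)
    return _simulate(config, config.n_patients, rng)


@dataclass
class TruthResult:
    """Ground-truth counterfactual quantities from forced-regimen replay."""

    outcome: str
    regimen_label: str
    cuminc_regimen: np.ndarray  # cumulative incidence at months 1..max_months
    cuminc_never: np.ndarray
    hazard_ratio: float
    log_hazard_ratio: float


def _first_event_rows(panel: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Person-months at risk for the first event of the given outcome
    (rows strictly after a patient's first event are dropped)."""
    col = f"event_{outcome}"
    ev = panel[col].astype(int)
    cum = ev.groupby(panel["patient_id"], sort=False).cumsum()
    prior = (cum - ev) > 0
    return panel[~prior.to_numpy()].copy()


def _discrete_cuminc(panel: pd.DataFrame, outcome: str, max_months: int) -> np.ndarray:
    at_risk = _first_event_rows(panel, outcome)
    haz = np.zeros(max_months)
    grp = at_risk.groupby("month")[f"event_{outcome}"]
    n_t = grp.size()
    e_t = grp.sum()
    for m in n_t.index:
        haz[m] = e_t[m] / n_t[m]
    return 1.0 - np.cumprod(1.0 - haz)


def counterfactual_truth(config: SimConfig, regimen: Regimen, n_mc: int,
                         outcome: str = "stroke") -> TruthResult:
    """True counterfactual risk curves and marginal hazard ratio vs never.

    Replays the generative model twice with treatment forced (initiate the
    first month the score reaches the threshold; never otherwise), then fits
    an unweighted pooled logistic regression of the first-event indicator on
    an arm indicator plus linear+quadratic month to summarise the marginal
    hazard ratio.  Deterministic given config.seed.
    """
    if n_mc < 1000:
        raise InputError("n_mc must be >= 1000")
    if outcome not in ("stroke", "bleed"):
        raise InputError(f"outcome must be 'stroke' or 'bleed', got {outcome!r}")
    panel_r = _simulate(config, n_mc, np.random.default_rng([config.seed, 1]),
                        forced=regimen)
    panel_n = _simulate(config, n_mc, np.random.default_rng([config.seed, 2]),
                        forced=Regimen("never"))
    ci_r = _discrete_cuminc(panel_r, outcome, config.max_months)
    ci_n = _discrete_cuminc(panel_n, outcome, config.max_months)

    rows_r = _first_event_rows(panel_r, outcome)
    rows_n = _first_event_rows(panel_n, outcome)
    rows_r = rows_r.assign(arm=1.0)
    rows_n = rows_n.assign(arm=0.0)
    pooled = pd.concat([rows_r, rows_n], ignore_index=True)
    exog = pd.DataFrame({
        "const": 1.0,
        "arm": pooled["arm"],
        "month": pooled["month"].astype(float),
        "month2": pooled["month"].astype(float) ** 2,
    })
    fit = sm.GLM(pooled[f"event_{outcome}"].astype(float), exog,
                 family=sm.families.Binomial()).fit()
    log_hr = float(fit.params["arm"])
    return TruthResult(outcome=outcome, regimen_label=regimen.label,
                       cuminc_regimen=ci_r, cuminc_never=ci_n,
                       hazard_ratio=float(np.exp(log_hr)),
                       log_hazard_ratio=log_hr)
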