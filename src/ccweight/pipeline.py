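"""End-to-end orchestration: simulate/load -> score -> eligibility ->
clone/censor -> weight -> estimate, with manifest-based reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cloning import build_clone_panel, default_regimens, expand_clones
from .eligibility import EligibilityCriteria, apply_eligibility
from .errors import ConfigError, DataError
from .estimation import (fit_outcome_model, person_time_summary, summary_hr,
                         survival_curves)
from .scores import score_panel
from .simulate import PANEL_COLUMNS, SimConfig, simulate_cohort
from .weights import (CovariateSpec, compute_cumulative_weights,
                      fit_weight_models, truncate_weights, weight_diagnostics)

log = logging.getLogger("ccweight")

REQUIRED_PANEL_COLUMNS = PANEL_COLUMNS


@dataclass(frozen=True)
class RunConfig:
    """One emulation run: inputs, strategy set, and analysis knobs."""

    simulation: SimConfig | None = None
    input_panel: str | None = None
    out_dir: str | None = None
    thresholds: tuple = (1, 2, 4, 6)
    include_never: bool = True
    grace_months: int = 1
    follow_up_months: int = 12
    truncation_percentile: float = 99.0
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    outcomes: tuple = ("stroke", "bleed")
    subgroup: tuple | None = None  # (column, value) filter at baseline
    drop_metastatic: bool = False
    drop_thrombocytopenia: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.simulation is None and self.input_panel is None:
            raise ConfigError("either simulation config or input_panel is required")
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise ConfigError("thresholds must be strictly increasing")
        if self.follow_up_months < 1:
            raise ConfigError("follow_up_months must be >= 1")
        if self.grace_months < 0:
            raise ConfigError("grace_months must be >= 0")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = dataclasses.asdict(self.covariates)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimConfig.from_dict(d["simulation"])
        if d.get("covariates") is not None:
            cov = d["covariates"]
            if isinstance(cov, dict):
                cov = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in cov.items()}
                d["covariates"] = CovariateSpec(**cov)
        for key in ("thresholds", "outcomes"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if isinstance(d.get("subgroup"), list):
            d["subgroup"] = tuple(d["subgroup"])
        return cls(**d)


@dataclass
class EmulationResult:
    """Everything one run produces, in memory; `write` persists it as CSVs
    plus a JSON manifest."""

    config: RunConfig
    attrition: pd.DataFrame
    person_time: dict          # outcome -> DataFrame
    adjusted_hr: dict          # outcome -> DataFrame
    unadjusted_hr: dict        # outcome -> DataFrame
    curves: dict               # outcome -> DataFrame
    weight_summary: pd.DataFrame
    manifest: dict

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {"attrition.csv": self.attrition,
                  "weight_diagnostics.csv": self.weight_summary}
        for outcome in self.person_time:
            tables[f"person_time_{outcome}.csv"] = self.person_time[outcome]
            tables[f"hr_adjusted_{outcome}.csv"] = self.adjusted_hr[outcome]
            tables[f"hr_unadjusted_{outcome}.csv"] = self.unadjusted_hr[outcome]
            tables[f"survival_{outcome}.csv"] = self.curves[outcome]
        digests = {}
        for name, df in tables.items():
            text = df.to_csv(index=False, float_format="%.10g")
            (out / name).write_text(text)
            digests[name] = hashlib.md5(text.encode()).hexdigest()
        manifest = dict(self.manifest)
        manifest["files"] = digests
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True, default=str))
        return out


def read_panel_csv(path: str | Path) -> pd.DataFrame:
    """Read a person-month panel CSV, failing fast on missing columns or
    missing values (imputation is out of scope)."""
    panel = pd.read_csv(path)
    missing = [c for c in REQUIRED_PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise DataError(f"input panel is missing required columns: {missing}")
    if panel[REQUIRED_PANEL_COLUMNS].isna().any().any():
        bad = [c for c in REQUIRED_PANEL_COLUMNS if panel[c].isna().any()]
        raise DataError(
            f"input panel contains missing values in {bad}; this pipeline "
            "does not impute — provide complete data")
    bool_cols = [c for c in REQUIRED_PANEL_COLUMNS
                 if c not in ("patient_id", "month", "age", "cancer_type",
                              "cancer_stage", "comorbidity_score",
                              "chads_vasc", "has_bled")]
    for c in bool_cols:
        panel[c] = panel[c].astype(bool)
    return panel


def write_panel_csv(panel: pd.DataFrame, path: str | Path) -> None:
    panel[REQUIRED_PANEL_COLUMNS].to_csv(path, index=False)


def _load_panel(config: RunConfig) -> pd.DataFrame:
    if config.simulation is not None:
        sim = config.simulation.replace(max_months=config.follow_up_months,
                                        seed=config.seed)
        return simulate_cohort(sim)
    panel = read_panel_csv(config.input_panel)
    return panel[panel["month"] < config.follow_up_months].copy()


def _baseline_filter(panel: pd.DataFrame, column: str, keep: pd.Series) -> pd.DataFrame:
    base = panel[panel["month"] == 0]
    kept_ids = base.loc[keep.loc[base.index], "patient_id"]
    return panel[panel["patient_id"].isin(kept_ids)].copy()


def run_emulation(config: RunConfig) -> EmulationResult:
    """Execute every stage in order for both outcomes.

    Re-running with the same config (same manifest) reproduces outputs
    bit-identically: the only randomness is the simulation seed.
    """
    panel = _load_panel(config)
    counts = {"panel_rows": len(panel),
              "patients": int(panel["patient_id"].nunique())}
    log.info("stage=load rows=%d patients=%d", counts["panel_rows"], counts["patients"])

    if config.subgroup is not None:
        col, value = config.subgroup
        panel = _baseline_filter(panel, col, panel[col] == value)
    if config.drop_metastatic:
        panel = _baseline_filter(panel, "cancer_stage",
                                 panel["cancer_stage"] != "distant")
    if config.drop_thrombocytopenia:
        panel = _baseline_filter(panel, "thrombocytopenia",
                                 ~panel["thrombocytopenia"].astype(bool))
    counts["after_filters_patients"] = int(panel["patient_id"].nunique())

    panel = score_panel(panel)
    eligible, attrition = apply_eligibility(panel, EligibilityCriteria())
    counts["eligible_patients"] = int(eligible["patient_id"].nunique())
    log.info("stage=eligibility\n%s", attrition)

    regimens = default_regimens(config.thresholds, config.include_never)
    clones = build_clone_panel(eligible, regimens, config.grace_months)
    counts["clone_rows"] = len(clones)
    counts["clones"] = int(clones.groupby(["patient_id", "regimen"]).ngroups) if len(clones) else 0
    counts["pre_exclusion_clones"] = len(regimens) * counts["eligible_patients"]
    log.info("stage=cloning clones=%d rows=%d", counts["clones"], counts["clone_rows"])

    wmodel = fit_weight_models(eligible, config.covariates)
    clones = compute_cumulative_weights(clones, wmodel, regimens,
                                        config.grace_months)
    clones = truncate_weights(clones, config.truncation_percentile)
    wsum = weight_diagnostics(clones)
    counts["weighted_clone_months"] = int((~clones["artificially_censored"]).sum())

    person_time, adj, unadj, curves = {}, {}, {}, {}
    for outcome in config.outcomes:
        person_time[outcome] = person_time_summary(clones, outcome)
        fit_w = fit_outcome_model(clones, outcome, weight_col="truncated_weight")
        adj[outcome] = summary_hr(fit_w)
        fit_u = fit_outcome_model(clones, outcome, weight_col=None)
        unadj[outcome] = summary_hr(fit_u)
        curves[outcome] = survival_curves(fit_w, clones)
        log.info("stage=estimation outcome=%s arms=%d", outcome,
                 len(adj[outcome]))

    manifest = {"config": config.to_dict(), "seed": config.seed,
                "version": __version__, "counts": counts}
    result = EmulationResult(config=config, attrition=attrition.to_frame(),
                             person_time=person_time, adjusted_hr=adj,
                             unadjusted_hr=unadj, curves=curves,
                             weight_summary=wsum, manifest=manifest)
    if config.out_dir:
        result.write(config.out_dir)
    return result


SENSITIVITY_VARIANTS = ("followup_36", "no_metastatic",
                        "no_thrombocytopenia", "truncation_95")


def run_sensitivity_suite(config: RunConfig) -> dict:
    """The four protocol sensitivity analyses, each one toggled field away
    from the base config; returns {variant: EmulationResult} plus a
    side-by-side adjusted-HR comparison table under key 'comparison'."""
    variants = {
        "followup_36": config.replace(follow_up_months=36),
        "no_metastatic": config.replace(drop_metastatic=True),
        "no_thrombocytopenia": config.replace(drop_thrombocytopenia=True),
        "truncation_95": config.replace(truncation_percentile=95.0),
    }
    results = {}
    comparison = []
    for name, vconf in variants.items():
        if config.out_dir:
            vconf = vconf.replace(out_dir=str(Path(config.out_dir) / name))
        results[name] = run_emulation(vconf)
        results[name].manifest["variant"] = name
        for outcome, table in results[name].adjusted_hr.items():
            t = table.copy()
            t.insert(0, "outcome", outcome)
            t.insert(0, "variant", name)
            comparison.append(t)
    results["comparison"] = pd.concat(comparison, ignore_index=True)
    if config.out_dir:
        results["comparison"].to_csv(Path(config.out_dir) / "sensitivity_comparison.csv",
                                     index=False)
    return results


__all__ = ["RunConfig", "EmulationResult", "run_emulation",
           "run_sensitivity_suite", "read_panel_csv", "write_panel_csv",
           "expand_clones"]
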