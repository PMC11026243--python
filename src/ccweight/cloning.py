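"""Clone expansion, baseline-compliance exclusion and artificial censoring.

Each eligible patient is copied once per strategy ("clone").  A clone whose
month-0 state already violates its strategy is deleted outright; a clone that
deviates later is artificially censored at the deviation month.  Censoring
takes precedence over outcomes within a month, so events in the deviation
month are not counted for the deviating clone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError


@dataclass(frozen=True)
class Regimen:
    """A treatment strategy: initiate when the score first reaches ``k``,
    or never initiate."""

    kind: str  # "threshold" | "never"
    k: int | None = None
    label: str = field(default="")

    def __post_init__(self):
        if self.kind not in ("threshold", "never"):
            raise ConfigError(f"regimen kind must be 'threshold' or 'never', got {self.kind!r}")
        if self.kind == "threshold":
            if self.k is None or not (1 <= int(self.k) <= 9):
                raise ConfigError(f"threshold k must be in 1..9, got {self.k!r}")
        elif self.k is not None:
            raise ConfigError("never-regimen must not carry a threshold k")
        if not self.label:
            object.__setattr__(
                self, "label", "never" if self.kind == "never" else f"ge{self.k}"
            )


def default_regimens(thresholds=(1, 2, 4, 6), include_never=True) -> list[Regimen]:
    """The five strategies of the primary analysis by default."""
    regimens = [Regimen("threshold", k) for k in thresholds]
    if include_never:
        regimens.append(Regimen("never"))
    return regimens


def expand_clones(panel: pd.DataFrame, regimens: list[Regimen]) -> pd.DataFrame:
    """Cross-product of eligible patients x regimens.

    Every clone starts as an exact copy of its source patient's rows, plus a
    ``regimen`` label column.  Row order is (patient_id, regimen, month).
    """
    if len(regimens) == 0:
        raise ConfigError("at least one regimen is required")
    labels = [r.label for r in regimens]
    if len(set(labels)) != len(labels):
        raise ConfigError(f"duplicate regimen labels: {labels}")
    if len(panel) == 0:
        out = panel.copy()
        out["regimen"] = pd.Series([], dtype=object)
        return out
    pieces = []
    for r in regimens:
        piece = panel.copy()
        piece["regimen"] = r.label
        pieces.append(piece)
    clones = pd.concat(pieces, ignore_index=True)
    return clones.sort_values(["patient_id", "regimen", "month"], kind="mergesort").reset_index(drop=True)


def assess_compliance(history: pd.DataFrame, regimen: Regimen,
                      grace_months: int = 1) -> tuple[bool, int | None]:
    """Evaluate one clone's history against its regimen.

    Returns ``(compliant, deviation_month)``; ``deviation_month`` is the
    first month the rule is violated, or None.

    Rules — threshold-k regimen: deviation if initiation occurs in a month
    before the score has ever reached k, or if the score first reaches k at
    month t0 and initiation has not happened by month t0 + grace_months
    (the deviation is detected at that deadline month, provided the clone is
    still under observation then).  Never-regimen: deviation at the month of
    initiation.
    """
    if len(history) == 0:
        return True, None
    h = history.sort_values("month")
    on = h["on_oac"].to_numpy(dtype=bool)
    if np.any(np.diff(on.astype(int)) < 0):
        raise DataError("on_oac must be absorbing (non-decreasing) within a clone")
    months = h["month"].to_numpy()
    init = h["initiated_this_month"].to_numpy(dtype=bool)
    first_init = int(months[init][0]) if init.any() else None

    if regimen.kind == "never":
        if first_init is not None:
            return False, first_init
        return True, None

    crossed = h["chads_vasc"].to_numpy() >= regimen.k
    t0 = int(months[crossed][0]) if crossed.any() else None
    if first_init is not None and (t0 is None or first_init < t0):
        return False, first_init  # premature initiation
    if t0 is not None:
        deadline = t0 + grace_months
        if (first_init is None or first_init > deadline) and months[-1] >= deadline:
            return False, deadline  # failed to initiate by the deadline
    return True, None


def _per_clone_deviation(clones: pd.DataFrame, regimens: list[Regimen],
                         grace_months: int) -> pd.DataFrame:
    """Vectorised deviation month per (patient, regimen) clone.

    Clone data equal the source patient's data before any censoring, so the
    patient-level aggregates (first initiation month, first crossing month
    per threshold, last observed month) determine each clone's deviation.
    """
    by_pat = clones[clones["regimen"] == regimens[0].label]
    g = by_pat.groupby("patient_id", sort=True)
    last_month = g["month"].max()
    init_months = by_pat.loc[by_pat["initiated_this_month"], ["patient_id", "month"]]
    first_init = init_months.groupby("patient_id")["month"].min()

    records = []
    for r in regimens:
        dev = pd.Series(np.nan, index=last_month.index)
        fi = first_init.reindex(last_month.index)
        if r.kind == "never":
            dev = fi.astype(float)
        else:
            crossed = by_pat.loc[by_pat["chads_vasc"] >= r.k, ["patient_id", "month"]]
            t0 = crossed.groupby("patient_id")["month"].min().reindex(last_month.index)
            premature = fi.notna() & (t0.isna() | (fi < t0))
            dev[premature] = fi[premature]
            deadline = t0 + grace_months
            late = (
                ~premature
                & t0.notna()
                & (fi.isna() | (fi > deadline))
                & (last_month >= deadline)
            )
            dev[late] = deadline[late]
        rec = pd.DataFrame({
            "patient_id": last_month.index,
            "regimen": r.label,
            "deviation_month": dev.to_numpy(),
        })
        records.append(rec)
    return pd.concat(records, ignore_index=True)


def apply_baseline_exclusion(clones: pd.DataFrame, regimens: list[Regimen],
                             grace_months: int = 1) -> pd.DataFrame:
    """Delete clones whose month-0 state already violates their regimen.

    Baseline violations are deletions, not censorings; every retained clone
    is annotated with its (future) deviation month, if any.
    """
    if len(clones) == 0:
        out = clones.copy()
        out["deviation_month"] = pd.Series([], dtype=float)
        return out
    dev = _per_clone_deviation(clones, regimens, grace_months)
    out = clones.merge(dev, on=["patient_id", "regimen"], how="left", sort=False)
    baseline_bad = out["deviation_month"] == 0
    out = out[~baseline_bad]
    return out.sort_values(["patient_id", "regimen", "month"], kind="mergesort").reset_index(drop=True)


def apply_artificial_censoring(clones: pd.DataFrame) -> pd.DataFrame:
    """Truncate each clone at its deviation month.

    Rows strictly after the deviation month are dropped.  The deviation-month
    row is kept, flagged ``artificially_censored``, with its outcome events
    zeroed (censoring precedes outcomes within the month); downstream stages
    exclude flagged rows from all risk sets.
    """
    out = clones.copy()
    if len(out) == 0:
        out["artificially_censored"] = pd.Series([], dtype=bool)
        out["censor_month"] = pd.Series([], dtype=float)
        return out
    dev = out["deviation_month"]
    keep = dev.isna() | (out["month"] <= dev)
    out = out[keep].copy()
    out["artificially_censored"] = out["month"] == out["deviation_month"]
    out.loc[out["artificially_censored"], ["event_stroke", "event_bleed"]] = False
    out["censor_month"] = out["deviation_month"]
    return out.reset_index(drop=True)


def build_clone_panel(panel: pd.DataFrame, regimens: list[Regimen],
                      grace_months: int = 1) -> pd.DataFrame:
    """expand -> baseline exclusion -> artificial censoring, in one call."""
    clones = expand_clones(panel, regimens)
    clones = apply_baseline_exclusion(clones, regimens, grace_months)
    return apply_artificial_censoring(clones)
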