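"""Baseline inclusion/exclusion criteria with flowchart-style attrition.

Criteria are applied sequentially in a fixed order; a patient excluded by an
earlier criterion is not re-counted by later ones (first-hit attribution),
so the log reads like a study flowchart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import SchemaError


@dataclass(frozen=True)
class EligibilityCriteria:
    """Order matters: age, enrollment, then the baseline exclusion flags."""

    min_age: int = 66
    require_continuous_enrollment: bool = True
    exclusion_flags: tuple = (
        "prior_oac",
        "valvular_disease",
        "recent_stroke_14d",
        "recent_surgery_bleed_30d",
        "esrd",
    )


@dataclass
class AttritionLog:
    """Ordered (criterion, n removed, n remaining) records."""

    initial: int
    steps: list = field(default_factory=list)

    def record(self, criterion: str, n_removed: int, n_remaining: int):
        self.steps.append((criterion, int(n_removed), int(n_remaining)))

    @property
    def final(self) -> int:
        return self.steps[-1][2] if self.steps else self.initial

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps,
                            columns=["criterion", "n_removed", "n_remaining"])

    def __str__(self) -> str:
        lines = [f"initial cohort: {self.initial}"]
        for crit, rem, left in self.steps:
            lines.append(f"  - {crit}: removed {rem}, remaining {left}")
        return "\n".join(lines)


def apply_eligibility(panel: pd.DataFrame, criteria: EligibilityCriteria
                      | None = None) -> tuple[pd.DataFrame, AttritionLog]:
    """Remove whole patients failing any baseline criterion.

    Conservation and idempotence hold: removed + retained = input patients,
    and a second application removes nobody.
    """
    criteria = criteria or EligibilityCriteria()
    needed = {"patient_id", "month", "age"} | set(criteria.exclusion_flags)
    if criteria.require_continuous_enrollment:
        needed.add("continuous_enrollment")
    missing = sorted(needed - set(panel.columns))
    if missing:
        raise SchemaError(f"panel is missing required columns: {missing}")

    baseline = panel[panel["month"] == 0].set_index("patient_id")
    log = AttritionLog(initial=len(baseline))
    alive = baseline.index
    checks = [("age under minimum",
               baseline["age"] < criteria.min_age)]
    if criteria.require_continuous_enrollment:
        checks.append(("no continuous enrollment",
                       ~baseline["continuous_enrollment"].astype(bool)))
    for flag in criteria.exclusion_flags:
        checks.append((flag, baseline[flag].astype(bool)))

    for name, fails in checks:
        dropped = alive.intersection(baseline.index[fails])
        alive = alive.difference(dropped, sort=False)
        log.record(name, len(dropped), len(alive))

    out = panel[panel["patient_id"].isin(alive)].copy()
    out["eligible"] = True
    return out.reset_index(drop=True), log
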