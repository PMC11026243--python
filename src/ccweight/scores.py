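"""Integer stroke-risk (CHA2DS2-VASc) and bleeding-risk (HAS-BLED) scores.

Both scores are pure functions of covariate flags and age, vectorised over
numpy arrays / pandas columns; scalars work too.  The HAS-BLED variant here
is the 7-component claims adaptation: the labile-INR component is omitted
because lab values are not observable in claims data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError, SchemaError

#: CHA2DS2-VASc condition flags worth points (besides age band and sex).
CHADS_FLAG_COLUMNS = [
    "chf",
    "hypertension",
    "diabetes",
    "prior_stroke_tia",
    "vascular_disease",
]

#: HAS-BLED condition flags (age band handled separately; labile INR omitted).
HASBLED_FLAG_COLUMNS = [
    "hypertension",
    "renal_abnormal",
    "liver_abnormal",
    "prior_stroke_tia",
    "bleeding_history",
    "drugs_alcohol",
]


def _check_age(age):
    age = np.asarray(age)
    if np.any(age < 0):
        raise InputError("age must be non-negative")
    return age


def chads_vasc(age, female, chf, hypertension, diabetes, prior_stroke_tia,
               vascular_disease):
    """CHA2DS2-VASc score in [0, 9].

    Points: CHF 1, hypertension 1, age >= 75 2 (else 65-74 1), diabetes 1,
    prior stroke/TIA/thromboembolism 2, vascular disease 1, female sex 1.
    The two age bands are mutually exclusive.
    """
    age = _check_age(age)
    age_points = np.where(age >= 75, 2, np.where(age >= 65, 1, 0))
    score = (
        age_points
        + np.asarray(chf, dtype=int)
        + np.asarray(hypertension, dtype=int)
        + np.asarray(diabetes, dtype=int)
        + 2 * np.asarray(prior_stroke_tia, dtype=int)
        + np.asarray(vascular_disease, dtype=int)
        + np.asarray(female, dtype=int)
    )
    return score if score.ndim else int(score)


def has_bled(age, hypertension, renal_abnormal, liver_abnormal,
             prior_stroke_tia, bleeding_history, drugs_alcohol):
    """Claims-adapted HAS-BLED score in [0, 7] (labile INR omitted).

    Points: hypertension 1, abnormal renal 1, abnormal liver 1, prior stroke
    1, bleeding history 1, age > 65 1, drugs/alcohol 1.
    """
    age = _check_age(age)
    score = (
        (age > 65).astype(int)
        + np.asarray(hypertension, dtype=int)
        + np.asarray(renal_abnormal, dtype=int)
        + np.asarray(liver_abnormal, dtype=int)
        + np.asarray(prior_stroke_tia, dtype=int)
        + np.asarray(bleeding_history, dtype=int)
        + np.asarray(drugs_alcohol, dtype=int)
    )
    return score if score.ndim else int(score)


def score_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Recompute ``chads_vasc`` and ``has_bled`` columns row-wise.

    Raises :class:`SchemaError` if any required flag column is missing.
    Given absorbing flags and non-decreasing age, the recomputed
    ``chads_vasc`` is non-decreasing within patient.
    """
    required = (
        {"age", "female"} | set(CHADS_FLAG_COLUMNS) | set(HASBLED_FLAG_COLUMNS)
    )
    missing = sorted(required - set(panel.columns))
    if missing:
        raise SchemaError(f"panel is missing required columns: {missing}")
    out = panel.copy()
    out["chads_vasc"] = chads_vasc(
        out["age"], out["female"], out["chf"], out["hypertension"],
        out["diabetes"], out["prior_stroke_tia"], out["vascular_disease"],
    )
    out["has_bled"] = has_bled(
        out["age"], out["hypertension"], out["renal_abnormal"],
        out["liver_abnormal"], out["prior_stroke_tia"],
        out["bleeding_history"], out["drugs_alcohol"],
    )
    return out
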