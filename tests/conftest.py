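import numpy as np
import pandas as pd
import pytest

from ccweight import SimConfig, simulate_cohort
from ccweight.simulate import PANEL_COLUMNS


def make_history(patient_id, scores, init_month=None, stroke_month=None,
                 bleed_month=None, death_month=None, dropout_month=None,
                 **overrides):
    """Hand-build one patient's person-month rows.

    `scores` is the chads_vasc trajectory; rows run from month 0 through the
    earliest of death/dropout/len(scores).  Flags default to False and are
    only there to satisfy the panel schema.
    """
    rows = []
    on = False
    for m, s in enumerate(scores):
        initiated = init_month is not None and m == init_month
        on = on or initiated
        row = {c: False for c in PANEL_COLUMNS}
        row.update({
            "patient_id": patient_id, "month": m, "age": 70, "female": False,
            "cancer_type": "breast", "cancer_stage": "local",
            "continuous_enrollment": True, "comorbidity_score": 0,
            "chads_vasc": s, "has_bled": 1,
            "on_oac": on, "initiated_this_month": initiated,
            "event_stroke": stroke_month == m, "event_bleed": bleed_month == m,
            "death": death_month == m, "dropout": dropout_month == m,
            "eligible": True,
        })
        row.update(overrides)
        rows.append(row)
        if death_month == m or dropout_month == m:
            break
    return pd.DataFrame(rows)[PANEL_COLUMNS]


def make_panel(histories):
    return pd.concat(histories, ignore_index=True)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_patients=300, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def medium_panel():
    return simulate_cohort(SimConfig(n_patients=5000, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
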