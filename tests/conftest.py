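import numpy as np
import pandas as pd
import pytest


def make_subjects(rows: list[dict]) -> pd.DataFrame:
    """Small hand-written cohort table with sensible defaults per row."""
    defaults = dict(age=65.0, sex="M", education=0.0, sbp=120.0, dbp=75.0,
                    t2dm=0.0, onset_report_1=np.nan, onset_report_2=np.nan,
                    onset_report_3=np.nan, menopause=np.nan,
                    hormone_therapy=np.nan, metformin=0.0,
                    other_t2dm_medication=0.0, bmi=27.0, head_size=1.0)
    records = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["id"] = f"S{i:03d}"
        rec.update(row)
        records.append(rec)
    return pd.DataFrame.from_records(records)


@pytest.fixture
def toy_cohort():
    """Six subjects covering the eligibility edge cases."""
    return make_subjects([
        {"sex": "F", "menopause": 1.0, "hormone_therapy": 0.0},
        {"sex": "F", "menopause": 0.0, "hormone_therapy": 0.0},   # premenopausal
        {"sex": "F", "menopause": 1.0, "hormone_therapy": 1.0},   # on HRT
        {"t2dm": 1.0, "onset_report_1": 38.0},                     # early onset
        {"t2dm": 1.0, "onset_report_1": 45.0, "onset_report_2": 47.0},
        {"sex": "M"},                                              # no menopause fields
    ])
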