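import numpy as np
import pandas as pd
import pytest

from hbref.cohort_io import FLAG_PREFIX, empty_cohort


def make_cohort(n=None, **columns) -> pd.DataFrame:
    """Build a canonical cohort frame from keyword columns, filling defaults.

    Flags are passed as e.g. ``flag_current_smoker=[True, None, ...]``.
    """
    if n is None:
        n = max(len(np.atleast_1d(v)) for v in columns.values()) if columns else 0
    base = {
        "participant_id": [f"p{i}" for i in range(n)],
        "source_id": "src",
        "age_years": 30.0,
        "sex": "male",
        "pregnant": None,
        "trimester": None,
        "haemoglobin_gL": 150.0,
        "ferritin_ugL": 60.0,
        "crp_mgL": 1.0,
        "mcv_fL": 88.0,
        "altitude_m": 0.0,
        "stratum": None,
        "psu": None,
        "weight": None,
    }
    data = {}
    for key, default in base.items():
        v = columns.get(key, default)
        data[key] = list(np.atleast_1d(v)) * n if np.ndim(v) == 0 else list(v)
    for key, v in columns.items():
        if key.startswith(FLAG_PREFIX):
            data[key] = list(np.atleast_1d(v)) * n if np.ndim(v) == 0 else list(v)
    frame = pd.DataFrame(data)
    frame["pregnant"] = frame["pregnant"].astype("boolean")
    frame["trimester"] = frame["trimester"].astype("Int64")
    for c in frame.columns:
        if c.startswith(FLAG_PREFIX):
            frame[c] = frame[c].astype("boolean")
    return frame


@pytest.fixture
def ten_record_fixture() -> pd.DataFrame:
    """Hand-built 10-record adult-male cohort: 2 missing labs, 1 iron
    deficient, 1 current smoker, 1 high altitude, 5 clean."""
    f = make_cohort(
        n=10,
        haemoglobin_gL=[148, 152, 149, 151, 150, 147, 153, 150, 149, 151],
        ferritin_ugL=[np.nan, 60, 10, 60, 60, 60, 60, 60, 60, 60],
        crp_mgL=[1, np.nan, 1, 1, 1, 1, 1, 1, 1, 1],
        altitude_m=[0, 0, 0, 0, 1000, 0, 0, 0, 0, 0],
        flag_current_smoker=[None, None, None, True, None, False, False,
                             False, False, False],
    )
    return f
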