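import datetime as dt

import numpy as np
import pandas as pd
import pytest

from prosmark.cohort import SubjectRecord


def make_record(
    subject_id="S1",
    gleason=(3, 4),
    psa_days_values=((90, 0.05), (180, 0.05)),
    surgery=dt.date(2001, 1, 1),
    last_contact_days=400,
    **flags,
):
    """Minimal valid subject record for endpoint/eligibility tests."""
    return SubjectRecord(
        subject_id=subject_id,
        age=62.0,
        preop_psa=6.5,
        gleason_primary=gleason[0],
        gleason_secondary=gleason[1],
        pT3=flags.get("pT3", False),
        pN1=flags.get("pN1", False),
        pR1=flags.get("pR1", False),
        surgery_date=surgery,
        psa_series=[
            (surgery + dt.timedelta(days=d), v) for d, v in psa_days_values
        ],
        last_contact=surgery + dt.timedelta(days=last_contact_days),
    )


@pytest.fixture
def small_survival_frame():
    """Deterministic 8-subject survival frame with two covariates, no ties."""
    rng = np.random.default_rng(42)
    n = 8
    return pd.DataFrame(
        {
            "time": np.round(rng.uniform(0.5, 6.0, n), 3),
            "event": [1, 0, 1, 1, 0, 1, 0, 1],
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
        }
    )


def random_survival_data(rng, n, p, tie_prob=0.0):
    """Random small survival dataset; optional tied event times."""
    if tie_prob > 0 and rng.uniform() < tie_prob:
        time = rng.integers(1, 4, size=n).astype(float)
    else:
        time = rng.uniform(0.2, 5.0, size=n)
    event = rng.uniform(size=n) < 0.7
    if not event.any():
        event[rng.integers(0, n)] = True
    X = rng.normal(size=(n, p)) * 0.8
    return time, event, X
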