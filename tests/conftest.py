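import numpy as np
import pandas as pd
import pytest

from migenv import ascertain, matching, synthetic


@pytest.fixture(scope="session")
def small_region():
    return synthetic.generate_region(6, 40, seed=1)


@pytest.fixture(scope="session")
def small_sources(small_region):
    return synthetic.generate_sources(small_region, n_emitters=20, n_wells=300, seed=2)


@pytest.fixture(scope="session")
def small_truth():
    return synthetic.TrueModel(
        intercept=-0.8,
        exposure_betas={"no2_per5": 0.2},
        county_sigma=0.25,
        severity=synthetic.SeverityParams(
            effects={"urgent_care": {"pm25_per5": 0.4}}
        ),
        seed=3,
    )


@pytest.fixture(scope="session")
def small_cohort(small_region, small_sources, small_truth):
    """(patients, events) for a 1500-patient cohort with events."""
    return synthetic.generate_cohort(small_region, small_sources, 1500, small_truth)


@pytest.fixture(scope="session")
def analysis_frame(small_cohort):
    """Scored, matched analysis frame with an arm indicator and outcomes."""
    patients, events = small_cohort
    scored = ascertain.score_cohort(events, patients["patient_id"])
    pats = patients.merge(scored[["patient_id", "is_case"]], on="patient_id")
    cohort = matching.frequency_match(
        pats[pats["is_case"]], pats[~pats["is_case"]], ratio=3, seed=11
    )
    frame = matching.matched_table(cohort, patients)
    frame["case"] = (frame["arm"] == "case").astype(int)
    severity = ascertain.severity_table(scored, patients)
    frame = frame.merge(
        severity.drop(columns=["person_years"]), on="patient_id", how="left"
    )
    return frame


def make_events(specs):
    """Events DataFrame from (patient_id, event_type, code, setting, med) tuples."""
    return pd.DataFrame(
        specs,
        columns=["patient_id", "event_type", "code", "care_setting", "med_class"],
    ).assign(date="2016-01-01")
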