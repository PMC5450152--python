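import numpy as np
import pandas as pd
import pytest

from pgxsig.datatypes import CLINICAL_COLUMNS, ClinicalTable
from pgxsig.simulate import make_fixture_cohort


@pytest.fixture(scope="session")
def fixture_cohort():
    return make_fixture_cohort(seed=1)


@pytest.fixture(scope="session")
def fixture_genotypes(fixture_cohort):
    return fixture_cohort[0]


@pytest.fixture(scope="session")
def fixture_clinical(fixture_cohort):
    return fixture_cohort[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_clinical_row(
    subject_id="S1",
    relapse_days=(),
    pre_relapses=2,
    history_years=2.0,
    exposure_years=1.0,
    baseline_edss=2.0,
    edss_series=None,
    new_t2=0,
    on_t1=0,
    brain_change=-0.1,
    **overrides,
):
    row = {
        "subject_id": subject_id,
        "cohort": "TEST",
        "arm": "active",
        "pre_study_relapses": pre_relapses,
        "history_years": history_years,
        "on_study_relapse_days": list(relapse_days),
        "exposure_years": exposure_years,
        "follow_up_days": 365.0,
        "baseline_edss": baseline_edss,
        "edss_series": edss_series or [(0.0, baseline_edss)],
        "baseline_t1_count": 1,
        "baseline_t1_status": 1,
        "baseline_t2_volume": 10.0,
        "new_t2_count": new_t2,
        "on_t1_count": on_t1,
        "t2_volume_change": 0.0,
        "brain_volume_change_pct": brain_change,
    }
    row.update(overrides)
    return row


def make_clinical_table(rows) -> ClinicalTable:
    df = pd.DataFrame(rows, columns=CLINICAL_COLUMNS)
    return ClinicalTable(df)
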