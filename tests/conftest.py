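import numpy as np
import pandas as pd
import pytest

import suddengain as sg


@pytest.fixture(scope="session")
def fixture_cohort() -> sg.SimCohort:
    """The packaged 146-participant replication fixture (built once)."""
    return sg.make_replication_fixture()


@pytest.fixture(scope="session")
def fixture_gains(fixture_cohort) -> pd.DataFrame:
    return sg.detect_cohort(fixture_cohort.cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20259)


@pytest.fixture()
def small_cohort() -> sg.Cohort:
    """Three hand-written participants: one clean gain, one flat, one sparse."""
    rows = []
    gain_series = [80, 75, 70, 60, 60, 60, 40, 40, 40, 38, 36, 35, 33, 30]
    for w, v in enumerate(gain_series, start=1):
        rows.append(("A", w, sg.LSAS, v))
    for w in range(1, 15):
        rows.append(("B", w, sg.LSAS, 80))
    for w in (1, 3, 5, 7, 9):
        rows.append(("C", w, sg.LSAS, 90))
    data = pd.DataFrame(rows, columns=["participant_id", "week", "measure", "value"])
    return sg.Cohort(data=data)
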