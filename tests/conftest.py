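import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from growthguard.cohort import CohortTable, TrajectoryMatrix, from_matrix

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_matrix(values, schedule=None, measure="zWFL") -> TrajectoryMatrix:
    values = np.asarray(values, float)
    n, k = values.shape
    schedule = schedule or tuple(float(2 * (j + 1)) for j in range(k))
    sids = tuple(f"S{i:03d}" for i in range(n))
    return TrajectoryMatrix(sids, values, schedule, measure)


def make_cohort(values, schedule=None, measure="zWFL") -> CohortTable:
    return from_matrix(make_matrix(values, schedule, measure))


@pytest.fixture
def small_cohort() -> CohortTable:
    """2 subjects x 3 visits, hand-written values."""
    frame = pd.DataFrame(
        {
            "subject_id": ["A", "A", "A", "B", "B", "B"],
            "visit_index": [0, 1, 2, 0, 1, 2],
            "age_months": [2.0, 4.0, 6.0, 2.0, 4.0, 6.0],
            "measure": "zWFL",
            "zscore": [0.1, 0.2, 0.3, -0.5, -0.4, -0.6],
        }
    )
    return CohortTable(frame, (2.0, 4.0, 6.0), "zWFL")


@pytest.fixture
def flat_cohort() -> CohortTable:
    """40 noiseless identical trajectories at z=0.3 over 8 visits."""
    return make_cohort(np.full((40, 8), 0.3))
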