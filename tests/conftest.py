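import numpy as np
import pandas as pd
import pytest

from microdyn import CohortSpec, generate_cohort
from microdyn.io import OtuTable


@pytest.fixture(scope="session")
def default_cohort():
    """The study-design cohort: 4 subjects, 5/8/5 time points, w_inside=0.5."""
    return generate_cohort(CohortSpec(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap cohort for structural tests."""
    return generate_cohort(
        CohortSpec(n_otus=60, n_timepoints_per_phase=(3, 4, 3),
                   depth_mean=5000, seed=11)
    )


@pytest.fixture()
def toy_table():
    """3 OTUs x 4 samples, two subjects, hand-checkable counts."""
    counts = pd.DataFrame(
        {
            "A1": [2, 2, 0],
            "A2": [1, 1, 2],
            "B1": [4, 0, 0],
            "B2": [0, 3, 1],
        },
        index=["otu1", "otu2", "otu3"],
    )
    meta = pd.DataFrame(
        {
            "subject": ["A", "A", "B", "B"],
            "time_point": [1, 2, 1, 2],
            "phase": [1, 2, 1, 2],
            "environment": ["outside", "inside", "outside", "inside"],
            "gender": ["male", "male", "female", "female"],
        },
        index=["A1", "A2", "B1", "B2"],
    )
    return OtuTable(counts, meta)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
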