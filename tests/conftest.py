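import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import bilemark as bm

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_table(values, kind="decimal", sample_ids=None, feature_ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    feature_ids = feature_ids or [f"f{j}" for j in range(p)]
    return bm.FeatureTable(pd.DataFrame(values, index=sample_ids, columns=feature_ids),
                           kind=kind)


def make_labels(groups, sample_ids=None):
    sample_ids = sample_ids or [f"s{i}" for i in range(len(groups))]
    return bm.CohortLabels(pd.Series(list(groups), index=sample_ids))


@pytest.fixture
def small_planted_cohort():
    """Two groups of 25, six features, a 3-SD effect planted on the first."""
    spec = bm.GroundTruthSpec(n_per_group=(25, 25), n_features=6,
                              planted_features=(0,), effect_size=3.0,
                              group_names=("benign", "CCA"), seed=7)
    return bm.generate_cohort(spec)


@pytest.fixture
def null_cohort():
    spec = bm.GroundTruthSpec(n_per_group=(20, 20), n_features=8,
                              effect_size=0.0, group_names=("benign", "CCA"),
                              seed=11)
    return bm.generate_cohort(spec)
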