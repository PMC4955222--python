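import numpy as np
import pandas as pd
import pytest

from sigstab import CompetingRisksDataset
from sigstab.synthetic import CohortSpec, generate_cohort


def make_dataset(time, event, event_type, expression=None, age=None,
                 prior_cv=None, endpoint="original"):
    """Hand-rolled tiny dataset for unit tests."""
    n = len(time)
    rng = np.random.default_rng(0)
    if expression is None:
        expression = rng.standard_normal((n, 3))
    expression = np.asarray(expression, dtype=float)
    if expression.ndim == 1:
        expression = expression[:, None]
    p = expression.shape[1]
    return CompetingRisksDataset(
        subject_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        time=np.asarray(time, dtype=float),
        event=np.asarray(event, dtype=int),
        event_type=np.asarray(event_type, dtype=int),
        clinical=pd.DataFrame({
            "age": np.full(n, 60.0) if age is None else np.asarray(age, float),
            "prior_cv": np.zeros(n) if prior_cv is None else np.asarray(prior_cv, float),
        }),
        expression=expression,
        feature_names=[f"f{j}" for j in range(p)],
        endpoint_version=endpoint,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """200 subjects x 100 features with 5 informative features per cause."""
    ds, gt = generate_cohort(CohortSpec(n=200, p=100, seed=42))
    return ds, gt


@pytest.fixture(scope="session")
def outlier_cohort():
    """Cohort with 3 injected magnitude-6 outlier subjects."""
    ds, gt = generate_cohort(CohortSpec(n=200, p=100, seed=43, n_outliers=3))
    return ds, gt
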