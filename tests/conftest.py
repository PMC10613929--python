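import numpy as np
import pandas as pd
import pytest

from moepheno.schema import CohortSchema, CohortTable, FeatureSpec
from moepheno.synthetic import default_amics_spec, generate_cohort


@pytest.fixture(scope="session")
def spec():
    return default_amics_spec()


@pytest.fixture(scope="session")
def cohort(spec):
    """Mid-size default cohort shared across read-only tests."""
    return generate_cohort(spec, 4_000, seed=42)


@pytest.fixture()
def tiny_schema():
    return CohortSchema(
        features=(
            FeatureSpec("age", "continuous", "presentation"),
            FeatureSpec("flag", "binary", "presentation"),
            FeatureSpec("dose", "continuous", "treatment"),
            FeatureSpec("device", "binary", "treatment"),
        ),
        outcome="died",
    )


@pytest.fixture()
def tiny_table(tiny_schema):
    df = pd.DataFrame(
        {
            "age": [1.0, 2.0, np.nan, 4.0],
            "flag": [1.0, np.nan, 0.0, 1.0],
            "dose": [0.5, 1.5, 2.5, np.nan],
            "device": [0.0, 1.0, 1.0, 0.0],
        }
    )
    return CohortTable(features=df, outcome=np.array([0, 1, 0, 1]), schema=tiny_schema)
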