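import numpy as np
import pandas as pd
import pytest

from clintrust.cohort import Cohort, FeatureSpec
from clintrust.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def acs_cohort() -> Cohort:
    """Mid-sized synthetic ACS cohort shared across model tests."""
    return generate_cohort(GeneratorConfig(n=500, seed=11))


@pytest.fixture()
def tiny_cohort() -> Cohort:
    """Six handmade patients: outcome equals (killip == 4)."""
    X = pd.DataFrame(
        {
            "age": [55.0, 62.0, 71.0, 80.0, 45.0, 68.0],
            "killip": [1, 2, 4, 4, 1, 3],
        }
    )
    y = np.array([0, 0, 1, 1, 0, 0])
    schema = [
        FeatureSpec("age", "numeric", "years"),
        FeatureSpec("killip", "ordinal", categories=(1, 2, 3, 4)),
    ]
    return Cohort(X, y, schema)
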