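import numpy as np
import pandas as pd
import pytest

from cogtraj import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Small default-mixture cohort shared across read-only tests."""
    return generate_cohort(GeneratorConfig.default(n_participants=60, seed=11))


@pytest.fixture(scope="session")
def recovery_cohort():
    """Identifiable single-class cohort for model-fit smoke tests."""
    return generate_cohort(GeneratorConfig.parameter_recovery(n_participants=40, seed=3))


@pytest.fixture(scope="session")
def blobs3():
    """Three well-separated spherical blobs (>= 10 SDs apart), n=90, d=4."""
    g = np.random.default_rng(0)
    centers = np.array(
        [
            [0.0, 0.0, 0.0, 0.0],
            [12.0, 0.0, 0.0, 0.0],
            [0.0, 12.0, 0.0, 0.0],
        ]
    )
    X = np.vstack([c + g.normal(0, 1.0, size=(30, 4)) for c in centers])
    labels = np.repeat([0, 1, 2], 30)
    return X, labels


@pytest.fixture(scope="session")
def person_params_frame():
    g = np.random.default_rng(5)
    n = 50
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:03d}" for i in range(n)],
            "alpha1": g.normal(0, 0.4, n),
            "alpha2": g.normal(-0.01, 0.02, n),
            "alpha3": g.normal(-0.1, 0.08, n),
            "tau": g.normal(63, 4, n),
        }
    )
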