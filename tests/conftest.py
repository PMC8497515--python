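import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from codigest import FeatureTable, make_reference_fixture, reference_ultimate_analyses

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def manures():
    """Validated reference compositions for the three manures."""
    return reference_ultimate_analyses()


@pytest.fixture(scope="session")
def reference_fixture():
    """Seeded synthetic bundle mirroring the 3-class x 3-replicate design."""
    return make_reference_fixture(seed=0)


@pytest.fixture()
def toy_table():
    """Small labelled 6-sample x 4-feature count table."""
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.integers(1, 200, size=(6, 4)),
        index=[f"s{i}" for i in range(6)],
        columns=[f"f{i}" for i in range(4)],
    ).astype(float)
    classes = pd.Series(["a", "a", "a", "b", "b", "b"], index=data.index)
    return FeatureTable(data=data, kind="pathway", classes=classes)
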