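import numpy as np
import pandas as pd
import pytest

from bbbqsar import LogBBModel, load_fixture, load_fixture_frame


@pytest.fixture(scope="session")
def fixture_records():
    return load_fixture()


@pytest.fixture(scope="session")
def fixture_frame():
    return load_fixture_frame()


@pytest.fixture(scope="session")
def eq4_results(fixture_frame):
    """The headline three-predictor fit on the bundled 126-compound table."""
    return LogBBModel.from_dataframe(fixture_frame).fit()


@pytest.fixture()
def toy_regression():
    """Small well-conditioned 2-predictor regression with known noise."""
    rng = np.random.default_rng(42)
    n = 12
    x1 = rng.uniform(0, 10, n)
    x2 = rng.uniform(-3, 3, n)
    y = 1.5 + 0.8 * x1 - 2.0 * x2 + rng.normal(0, 0.3, n)
    return pd.DataFrame({"x1": x1, "x2": x2, "y": y})
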