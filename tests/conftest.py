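import numpy as np
import pandas as pd
import pytest

from ratiotax import GENITAL_VARIABLES, MeasurementTable


def make_table(values, variables=None, groups=None, ids=None) -> MeasurementTable:
    """Build a MeasurementTable from a plain array."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if variables is None:
        variables = [f"v{k + 1}" for k in range(p)]
    if ids is None:
        ids = [f"s{k + 1}" for k in range(n)]
    if groups is None:
        groups = ["G"] * n
    frame = pd.DataFrame(values, index=ids, columns=list(variables))
    return MeasurementTable(frame, pd.Series(list(groups), index=ids))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_table(rng):
    """8 specimens x 4 variables of log-normal measurements, one group."""
    return make_table(np.exp(rng.normal(1.0, 0.3, size=(8, 4))))


@pytest.fixture
def two_group_table(rng):
    """Two groups of 8 specimens over the genital variable set."""
    vals = np.exp(rng.normal(1.0, 0.2, size=(16, len(GENITAL_VARIABLES))))
    groups = ["CAR"] * 8 + ["CLA"] * 8
    return make_table(vals, variables=GENITAL_VARIABLES, groups=groups)
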