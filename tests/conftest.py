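import numpy as np
import pandas as pd
import pytest

from corticell.io_ct import CtMatrix
from corticell.simdata import (
    QpcrSimConfig,
    make_worked_example_fixture,
    simulate_counts,
    simulate_qpcr,
)


@pytest.fixture(scope="session")
def worked_example():
    return make_worked_example_fixture()


@pytest.fixture(scope="session")
def sim_clean():
    """Dropout-free simulation with no failed wells: labels fully recoverable."""
    config = QpcrSimConfig(
        n_wells=200,
        composition={
            "deep-neuron": 0.3,
            "upper-neuron": 0.3,
            "mixed-neuron": 0.2,
            "markerless-neuron": 0.2,
        },
        dropout=1.0,
        seed=7,
    )
    return simulate_qpcr(config)


@pytest.fixture(scope="session")
def sim_counts_outliers():
    return simulate_counts(n_cells=50, n_genes=500, planted_outliers=4, seed=2)


@pytest.fixture()
def tiny_ct():
    ct = pd.DataFrame(
        [[25.0, 999.0, 18.0], [999.0, 999.0, 999.0]],
        index=["A", "B"],
        columns=["GAPDH", "ACTB", "MAP2"],
    )
    return CtMatrix(ct, pd.Series(["batch1", "batch1"], index=["A", "B"]))


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
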