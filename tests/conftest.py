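import numpy as np
import pandas as pd
import pytest

from priorfs.datasets import ExpressionDataset
from priorfs.simulate import (
    SimulationSpec,
    generate_association_kb,
    generate_expression,
    generate_network_kb,
)


@pytest.fixture(scope="session")
def small_spec():
    return SimulationSpec(
        n_samples=60, n_genes=200, n_informative=8,
        n_pathways=4, pathway_size=12, seed=7,
    )


@pytest.fixture(scope="session")
def small_fixture(small_spec):
    """(dataset, ground truth) with planted signal, shared across tests."""
    return generate_expression(small_spec)


@pytest.fixture(scope="session")
def small_ds(small_fixture):
    return small_fixture[0]


@pytest.fixture(scope="session")
def small_truth(small_fixture):
    return small_fixture[1]


@pytest.fixture(scope="session")
def small_kb(small_truth):
    return generate_association_kb(small_truth)


@pytest.fixture(scope="session")
def small_net(small_truth):
    return generate_network_kb(small_truth)


@pytest.fixture
def tiny_labeled_ds():
    """3 genes x 6 samples, two classes, hand-set values."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.standard_normal((3, 6)),
        index=["g1", "g2", "g3"],
        columns=[f"s{i}" for i in range(6)],
    )
    values.loc["g1", ["s0", "s1", "s2"]] += 5.0  # strong class signal
    labels = pd.Series(
        ["a", "a", "a", "b", "b", "b"], index=values.columns, name="condition"
    )
    return ExpressionDataset(values, labels)
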