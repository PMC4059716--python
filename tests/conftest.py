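import numpy as np
import pytest

from consensusfs import ExpressionMatrix, PhenotypeVector, SimConfig, simulate_dataset


@pytest.fixture
def small_planted():
    """20 samples, 30 probes, 2 planted at 3 SD: quick ranker recovery data."""
    config = SimConfig(
        n_probes=30, n_informative=2, n_case=10, n_control=10, effect=3.0, seed=7
    )
    return simulate_dataset(config)


@pytest.fixture
def tiny_matrix():
    values = np.arange(1.0, 7.0).reshape(2, 3)
    return ExpressionMatrix(["p1", "p2"], ["s1", "s2", "s3"], values)


@pytest.fixture
def two_group_labels():
    return PhenotypeVector(["s1", "s2", "s3", "s4"], np.array([1, 1, 0, 0]))
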