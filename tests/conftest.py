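import numpy as np
import pytest

from ctimpute import CountMatrix, GeneAnnotation, SimParams, simulate_dataset


@pytest.fixture
def toy_counts():
    """3 genes x 2 samples with one low-total gene."""
    return CountMatrix(
        ["gA", "gB", "gC"],
        ["s1", "s2"],
        np.array([[100, 200], [7, 7], [0, 0]]),
    )


@pytest.fixture
def toy_annotation():
    return GeneAnnotation({"gA": 1000, "gB": 2000, "gC": 500})


@pytest.fixture(scope="session")
def small_params():
    """Down-scaled simulation parameters for fast unit tests."""
    return SimParams(
        n_genes=80,
        pool_cells=1500,
        cells_per_type=500,
        mixture_total_cells=500,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return simulate_dataset(small_params, n_samples=40)
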