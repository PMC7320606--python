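import numpy as np
import pytest

from icgs2 import (
    ExpressionMatrix,
    FixtureConfig,
    NormState,
    generate_dataset,
    normalize_cptt,
)


@pytest.fixture(scope="session")
def small_fixture():
    """800-cell K=4 planted-cluster dataset with strong markers."""
    return generate_dataset(
        FixtureConfig(
            n_cells=800, n_genes=1500, n_clusters=4,
            markers_per_cluster=50, marker_fold=8.0, seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_normalized(small_fixture):
    return normalize_cptt(small_fixture.matrix)


@pytest.fixture
def tiny_counts():
    """4 genes x 4 cells of hand-checkable integer counts."""
    values = np.array(
        [
            [2.0, 0.0, 5.0, 1.0],
            [0.0, 3.0, 0.0, 2.0],
            [1.0, 1.0, 1.0, 1.0],
            [7.0, 6.0, 4.0, 6.0],
        ]
    )
    return ExpressionMatrix(
        ["GA", "GB", "GC", "GD"], ["c1", "c2", "c3", "c4"], values, NormState.raw_counts
    )
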