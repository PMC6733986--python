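import numpy as np
import pytest

from keranet.io import CountMatrix
from keranet.simulate import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced cohort used by unit tests (fast but structurally complete)."""
    return SimulationConfig(
        n_cells=640,
        n_genes=400,
        n_tfs=6,
        targets_per_tf=10,
        n_specific_genes=60,
        antioxidant_cluster_sizes=(10, 4, 4),
        n_bulk_samples=60,
        n_target_samples=3,
        n_se_per_state=20,
        se_length_range=(500, 1200),
        n_null_motifs=3,
        seed=42,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    # fresh, fixed-seed stream per test: results never depend on test order
    return np.random.default_rng(20240915)


@pytest.fixture()
def tiny_counts() -> CountMatrix:
    rng = np.random.default_rng(7)
    values = rng.integers(0, 20, size=(12, 9))
    values[:, 0] += 1  # no all-zero cell
    values[0] = 0  # one all-zero gene
    return CountMatrix(
        values,
        [f"g{i:02d}" for i in range(12)],
        [f"c{i:02d}" for i in range(9)],
    )
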