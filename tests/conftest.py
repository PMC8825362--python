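import sys
from pathlib import Path

import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

# make the sibling oracle module importable from every test file
sys.path.insert(0, str(Path(__file__).parent))

from roinet import simulate  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but realistic two-group cohort with a planted effect."""
    config = simulate.SimulationConfig(
        n_per_group=8, n_regions=30, n_timepoints=120, n_blocks=3,
        effect_nodes=(2, 12, 22), effect_delta_r=0.3, seed=77,
    )
    return simulate.simulate_cohort(config), config


@pytest.fixture(scope="session")
def null_cohort():
    """Two groups drawn from the same population (no effect)."""
    config = simulate.SimulationConfig(
        n_per_group=8, n_regions=30, n_timepoints=120, n_blocks=3,
        effect_nodes=(), effect_delta_r=0.0, seed=78,
    )
    return simulate.simulate_cohort(config), config


# canonical tiny graphs used across metric tests
def complete_graph(n: int) -> np.ndarray:
    a = np.ones((n, n), dtype=np.uint8)
    np.fill_diagonal(a, 0)
    return a


def star_graph(n: int) -> np.ndarray:
    """Hub node 0 connected to n-1 leaves."""
    a = np.zeros((n, n), dtype=np.uint8)
    a[0, 1:] = 1
    a[1:, 0] = 1
    return a


def path_graph(n: int) -> np.ndarray:
    a = np.zeros((n, n), dtype=np.uint8)
    idx = np.arange(n - 1)
    a[idx, idx + 1] = 1
    a[idx + 1, idx] = 1
    return a


def ring_lattice(n: int, k: int) -> np.ndarray:
    """Ring of n nodes, each joined to its k nearest neighbors."""
    a = np.zeros((n, n), dtype=np.uint8)
    for shift in range(1, k // 2 + 1):
        idx = np.arange(n)
        a[idx, (idx + shift) % n] = 1
        a[(idx + shift) % n, idx] = 1
    return a
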