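import numpy as np
import pytest

from dtnet import load_worked_example
from dtnet.synth import GeneratorConfig, generate_random_network

# The illustrative 8x4 network's three indicator matrices, frozen cell-for-cell.
ACTIVE_MATRIX = np.array(
    [
        [1, 1, 0, 1],
        [0, 1, 1, 0],
        [1, 0, 0, 0],
        [1, 1, 1, 0],
        [0, 1, 0, 1],
        [1, 0, 0, 1],
        [1, 1, 1, 1],
        [0, 0, 1, 1],
    ]
)
INACTIVE_MATRIX = np.array(
    [
        [0, 0, 0, 0],
        [0, 0, 0, 1],
        [0, 0, 0, 1],
        [0, 0, 0, 1],
        [1, 0, 0, 0],
        [0, 1, 1, 0],
        [0, 0, 0, 0],
        [0, 1, 0, 0],
    ]
)
UNKNOWN_MATRIX = np.array(
    [
        [0, 0, 1, 0],
        [1, 0, 0, 0],
        [0, 1, 1, 0],
        [0, 0, 0, 0],
        [0, 0, 1, 0],
        [0, 0, 0, 0],
        [0, 0, 0, 0],
        [1, 0, 0, 0],
    ]
)

POLYPHARMACOLOGY = [3, 2, 1, 3, 2, 2, 4, 2]
POLYSPECIFICITY = [5, 5, 4, 5]
INACTIVE_ROW_SUMS = [0, 1, 1, 1, 1, 2, 0, 1]
INACTIVE_COL_SUMS = [1, 2, 1, 3]
UNKNOWN_ROW_SUMS = [1, 1, 2, 0, 1, 0, 0, 1]
UNKNOWN_COL_SUMS = [2, 1, 3, 0]
DRUG_BOUNDS = [(3, 4), (2, 3), (1, 3), (3, 3), (2, 3), (2, 2), (4, 4), (2, 3)]
TARGET_BOUNDS = [(5, 7), (5, 6), (4, 7), (5, 5)]


@pytest.fixture(scope="session")
def worked_example():
    return load_worked_example()


def random_networks(count, seed0=0, max_drugs=50, max_targets=30):
    """Seeded stream of random ternary networks with varied shapes and mixes."""
    rng = np.random.default_rng(seed0)
    for k in range(count):
        n = int(rng.integers(1, max_drugs + 1))
        m = int(rng.integers(1, max_targets + 1))
        raw = rng.dirichlet([1.0, 1.0, 1.0])
        p = raw / raw.sum()
        yield generate_random_network(
            GeneratorConfig(
                n_drugs=n,
                n_targets=m,
                p_active=float(p[0]),
                p_inactive=float(p[1]),
                p_unknown=float(1.0 - p[0] - p[1]),
                seed=seed0 + 1000 + k,
            )
        )
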