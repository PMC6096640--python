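import numpy as np
import pytest

from twopartsim.genome import GeneticMap, simulate_founders
from twopartsim.ocs import ibs_coancestry


@pytest.fixture(scope="session")
def small_map():
    return GeneticMap.regular(2, 10, 10, 1.0)


@pytest.fixture(scope="session")
def founders(small_map):
    return simulate_founders(40, small_map, rng_seed=11)


@pytest.fixture(scope="session")
def small_ocs_instance():
    """8 + 8 candidates, 4 crosses: fully enumerable."""
    rng = np.random.default_rng(42)
    n = 16
    a = rng.normal(0, 1, n)
    M = rng.integers(0, 3, (n, 50))
    return {
        "ids": np.array([f"c{i:02d}" for i in range(n)]),
        "a": a,
        "C": ibs_coancestry(M),
        "pool": np.array(["F"] * 8 + ["M"] * 8),
        "n_crosses": 4,
    }


def enumerate_contributions(n_pool: int, total: int, cap: int) -> np.ndarray:
    """All per-pool contribution vectors: entries 0..cap summing to total."""
    out = []

    def rec(i, left, cur):
        if i == n_pool:
            if left == 0:
                out.append(tuple(cur))
            return
        lo = max(0, left - cap * (n_pool - i - 1))
        for v in range(lo, min(cap, left) + 1):
            rec(i + 1, left - v, cur + [v])

    rec(0, total, [])
    return np.array(out)
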