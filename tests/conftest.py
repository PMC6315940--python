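import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_sparse_matrix(n: int, density: float, seed: int, max_p: float = 0.9):
    """Random symmetric sparse probability matrix with unit-capped rows."""
    from rnabound import BasePairMatrix

    rng = np.random.default_rng(seed)
    probs = {}
    row = np.zeros(n + 1)
    target = int(density * n * (n - 1) / 2)
    for _ in range(target * 3):
        if len(probs) >= target:
            break
        i = int(rng.integers(1, n))
        j = int(rng.integers(i + 1, n + 1))
        if (i, j) in probs:
            continue
        p = float(rng.uniform(0.0, max_p))
        if row[i] + p > 0.98 or row[j] + p > 0.98:
            continue
        probs[(i, j)] = p
        row[i] += p
        row[j] += p
    return BasePairMatrix(n, probs, source="synthetic")


@pytest.fixture
def make_matrix():
    return random_sparse_matrix
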