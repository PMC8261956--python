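import numpy as np
import pytest

from microstd import StratifiedDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def two_stratum_dataset(rng):
    """Small two-stratum dataset with 3 signal features out of 15."""
    n, p = 40, 15
    conf = np.array(["a"] * 20 + ["b"] * 20)
    counts = rng.poisson(10.0, size=(n, p))
    X = counts.astype(float)
    y = np.zeros(n)
    for lev in ("a", "b"):
        idx = np.where(conf == lev)[0]
        block = X[idx]
        A = (block - block.mean(0)) / block.std(0, ddof=1)
        y[idx] = A[:, 0] * 2.0 - A[:, 1] * 2.0 + A[:, 2] * 1.5
    y += rng.normal(0, 0.3, n)
    return StratifiedDataset(
        counts=counts,
        sample_ids=[f"s{i}" for i in range(n)],
        feature_ids=[f"f{j}" for j in range(p)],
        outcome=y,
        confounder=conf,
    )


def orthonormal_design(rng, n, p):
    """Centered design with X'X/n = I exactly."""
    M = rng.normal(size=(n, p))
    M -= M.mean(axis=0)
    Q, _ = np.linalg.qr(M)
    return Q[:, :p] * np.sqrt(n)
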