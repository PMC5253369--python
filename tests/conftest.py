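import numpy as np
import pytest

from decodemap import (
    EpochedDataset,
    MapEnsemble,
    MegSimConfig,
    ToyConfig,
    make_toy,
    normalize_map,
    simulate_meg,
)


@pytest.fixture(scope="session")
def toy_data():
    """Default-conditions toy dataset (1000 trials per class)."""
    return make_toy(ToyConfig(seed=7))


@pytest.fixture(scope="session")
def small_meg():
    """A reduced-geometry simulated MEG dataset for fast unit tests."""
    cfg = MegSimConfig(
        epochs_per_class=40, n_channels=24, n_times=100, seed=11
    )
    return simulate_meg(cfg)


def random_ensemble(rng, p=None, m=None, concentrated=False):
    """A random MapEnsemble, optionally clustered around one direction."""
    p = p if p is not None else int(rng.integers(2, 501))
    m = m if m is not None else int(rng.integers(2, 101))
    if concentrated:
        center = rng.normal(size=p)
        raw = center[None, :] + 0.3 * rng.normal(size=(m, p))
    else:
        raw = rng.normal(size=(m, p))
    maps = tuple(normalize_map(row) for row in raw)
    return MapEnsemble(maps, provenance={"scheme": "random", "seed": "test"})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def gaussian_dataset(rng, n=80, p=5, balanced=True, centered=True,
                     separation=1.0):
    """Full-rank Gaussian two-class data, optionally balanced and centered."""
    assert n % 2 == 0
    half = n // 2
    labels = np.concatenate([np.ones(half, int), -np.ones(half, int)])
    direction = rng.normal(size=p)
    direction /= np.linalg.norm(direction)
    X = rng.normal(size=(n, p)) + separation * labels[:, None] * direction
    if centered:
        X = X - X.mean(axis=0)
    return EpochedDataset(X, labels)
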