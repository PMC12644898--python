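import numpy as np
import pytest

from motifbag.gbt_models import TrainConfig, train
from motifbag.bag_matrix import MotifCountMatrix
from motifbag.pipeline import run_recovery
from motifbag.synthetic import make_motif_set

import pandas as pd


@pytest.fixture(scope="session")
def recovery():
    """Full-scale two-class motif-recovery benchmark (shared across tests)."""
    return run_recovery(seed=11)


@pytest.fixture(scope="session")
def random_pwms():
    """Ten seeded random PWMs with widths 6-12 for scanner oracles."""
    return make_motif_set(10, width_range=(6, 12), concentration=8.0, seed=5)


def _count_matrix(X, labels=None, prefix="r"):
    rows = [f"{prefix}{i}" for i in range(X.shape[0])]
    cols = [f"M{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(np.asarray(X, dtype=np.int64), index=rows, columns=cols)
    labs = {r: [str(l)] for r, l in zip(rows, labels)} if labels is not None else {}
    return MotifCountMatrix(df, labs)


@pytest.fixture
def count_matrix_factory():
    return _count_matrix


@pytest.fixture(scope="session")
def separable_model():
    """Binary model on 8 features where class = presence of M0; plus the data."""
    rng = np.random.default_rng(42)
    n = 200
    X = rng.integers(0, 4, size=(n, 8))
    y = (rng.random(n) < 0.5).astype(int)
    X[:, 0] = np.where(y == 1, rng.integers(1, 5, size=n), 0)
    split = int(n * 0.7)
    tr = _count_matrix(X[:split], prefix="t")
    va = _count_matrix(X[split:], prefix="v")
    config = TrainConfig(mode="binary", rounds=300, learning_rate=0.1, seed=0)
    bundle = train(tr, y[:split], va, y[split:], config)
    return bundle, tr, va, y
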