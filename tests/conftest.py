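import numpy as np
import pytest

from latloc import (KernelSpec, SyntheticConfig, TrainConfig, generate,
                    standardize)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Reference planted-subgroup cohort, standardized."""
    ds = generate(SyntheticConfig(seed=7))
    X, y, stats = standardize(ds.X_raw, ds.y_raw)
    return ds, X, y, stats


@pytest.fixture(scope="session")
def quick_train_config():
    """Short full-batch schedule for tests that need a trained model."""
    return TrainConfig(d=2, epochs=60, learning_rate=1e-2, seed=0,
                       variance_floor=0.05, kernel=KernelSpec())
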