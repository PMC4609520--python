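import dataclasses

import numpy as np
import pytest

import acucoder as ac
from acucoder.synth_clinic import zero_noise


@pytest.fixture(scope="session")
def small_cfg():
    return ac.default_config("small", seed=3)


@pytest.fixture(scope="session")
def zero_cfg(small_cfg):
    return zero_noise(small_cfg)


@pytest.fixture(scope="session")
def small_ds(small_cfg):
    return ac.generate_records(small_cfg)


@pytest.fixture(scope="session")
def zero_ds(zero_cfg):
    return ac.generate_records(zero_cfg)


@pytest.fixture(scope="session")
def zero_ds_held(zero_cfg):
    return ac.generate_records(dataclasses.replace(zero_cfg, seed=99))


@pytest.fixture(scope="session")
def zero_pool(zero_ds):
    """A small mixed pool trained on the zero-noise dataset."""
    return ac.train_pool(zero_ds, ac.PoolConfig(m_tree=4, m_margin=4, seed=1))


class FixedTupleLearner:
    """Test stub emitting fixed (icd10, tcm) predictions and acupoint plans."""

    def __init__(self, y, z, acupoints=None):
        self._y = np.asarray(y)
        self._z = np.asarray(z)
        self._acu = None if acupoints is None else np.asarray(acupoints)

    def predict_tuple(self, X):
        return self._y.copy(), self._z.copy()

    def predict_acupoints(self, X):
        return self._acu.copy()


@pytest.fixture
def fixed_learner_cls():
    return FixedTupleLearner
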