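import warnings

import numpy as np
import pytest

from kwlpr.dataio import fit_scaler
from kwlpr.fixtures import FixtureSpec, generate
from kwlpr.local_poly import KwlprModel


@pytest.fixture(scope="session")
def sine_ds():
    """Sinusoidal 1-D fixture: 60 train / 20 validation, 3:1 signal-to-noise."""
    ds, truth = generate(FixtureSpec("sine1d", n_train=60, n_valid=20, seed=1))
    return ds, truth


@pytest.fixture(scope="session")
def qsaar_ds():
    """Two correlated descriptors at the case-study-1 sample sizes."""
    ds, truth = generate(
        FixtureSpec("qsaar2d", n_train=254, n_valid=64,
                    descriptor_correlation=0.5, seed=1)
    )
    return ds, truth


@pytest.fixture(scope="session")
def linear_ds():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds, truth = generate(FixtureSpec("linear1d", n_train=25, n_valid=0, seed=3))
    return ds, truth


@pytest.fixture(scope="session")
def noise_ds():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds, truth = generate(FixtureSpec("noise_only", n_train=60, n_valid=0, seed=5))
    return ds, truth


@pytest.fixture()
def sine_model(sine_ds):
    """A sensible fixed-bandwidth Nadaraya-Watson model on the sine fixture."""
    ds, _ = sine_ds
    return KwlprModel.fit(ds, degree=0, kernel="gaussian", bandwidths=[0.3])


def scaled_train(ds):
    scaler = fit_scaler(ds)
    return scaler.transform(ds.X_train), ds.y_train


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
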