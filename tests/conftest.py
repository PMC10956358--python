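import numpy as np
import pytest

from qsarkit.synthetic import SimConfig, gen_qsar_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def strong_signal_dataset():
    """28 compounds, 4 descriptors, 23/5 split, linear signal, sd 0.15."""
    ds, truth = gen_qsar_dataset(SimConfig(seed=42, noise_sd=0.15))
    return ds, truth


def random_regression_problem(rng, n=25, p=4, noise_sd=0.3):
    X = rng.standard_normal((n, p))
    beta = rng.normal(0, 2, size=p)
    y = rng.normal(1.0) + X @ beta + rng.normal(0, noise_sd, size=n)
    return X, y
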