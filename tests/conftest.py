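import numpy as np
import pytest

from toxpod.synthetic import SyntheticSpec, make_synthetic_qsar, make_toy_fixture
from toxpod.uacqr import conformal_calibrate, fit_quantile_forest


@pytest.fixture(scope="session")
def toy_records():
    return make_toy_fixture()


@pytest.fixture(scope="session")
def synth_small():
    """Small cluster-structured dataset for fast model tests."""
    return make_synthetic_qsar(SyntheticSpec(n_chems=600, n_clusters=5, seed=7))


@pytest.fixture(scope="session")
def fitted_uacqr(synth_small):
    """qRF + conformal adjustment fitted on a train/cal split of synth_small."""
    d = synth_small
    X = d.descriptors.values
    tr, cal = slice(0, 400), slice(400, 500)
    model = fit_quantile_forest(X[tr], d.y[tr], n_trees=100, seed=3)
    adj = conformal_calibrate(model, X[cal], d.y[cal], level=0.95)
    return d, model, adj


def heteroscedastic_split(n_train=1000, n_cal=500, n_test=2000, seed=0, variance=0.69):
    """The standard heteroscedastic synthetic protocol used for coverage checks."""
    n = n_train + n_cal + n_test
    d = make_synthetic_qsar(
        SyntheticSpec(n_chems=n, target_variance_goal=variance, seed=seed)
    )
    X = d.descriptors.values
    idx = np.arange(n)
    tr = idx[:n_train]
    ca = idx[n_train : n_train + n_cal]
    te = idx[n_train + n_cal :]
    return d, X, tr, ca, te
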