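import numpy as np
import pytest

from devbrainmap import phantom


@pytest.fixture(scope="session")
def stock_spec():
    """Stock phantom layout at the default desk-scale grid."""
    return phantom.default_spec(seed=11)


@pytest.fixture(scope="session")
def stock_base(stock_spec):
    """Base (undeformed) phantom volume and labels, shared across tests."""
    return phantom.build_base(stock_spec)


@pytest.fixture(scope="session")
def small_spec():
    """Smaller grid for registration-heavy tests."""
    return phantom.default_spec(seed=7, shape=(48, 42, 32), deformation_um=30.0,
                                age_scales=(0.9,))


@pytest.fixture(scope="session")
def small_base(small_spec):
    return phantom.build_base(small_spec)


@pytest.fixture(scope="session")
def small_subject(small_spec):
    """One deformed subject with ground-truth transform, registration-scale."""
    return phantom.make_phantom_series(small_spec, 1, 1)[0][0]


def dice(a: np.ndarray, b: np.ndarray, label: int | None = None) -> float:
    """Dice overlap of two label images (foreground, or one label)."""
    if label is None:
        ma, mb = a > 0, b > 0
    else:
        ma, mb = a == label, b == label
    denom = ma.sum() + mb.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(ma, mb).sum() / denom
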