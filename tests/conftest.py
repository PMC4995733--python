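import numpy as np
import pytest

from redoxcys.features import FeatureSpec
from redoxcys.pipeline import encode_balanced
from redoxcys.synth import SynthConfig, generate


@pytest.fixture(scope="session")
def small_config():
    """A reduced synthetic study: quick to generate and encode."""
    return SynthConfig(
        n_proteins=20, length_range=(80, 200), n_positive_sites=30, seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def small_design(small_dataset):
    records, pssms, annotations = small_dataset.registries()
    return encode_balanced(
        small_dataset.site_table, FeatureSpec(), records, pssms, annotations, seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def planted_signal(n=100, p=10, informative=(0, 1), margin=0.4, seed=0):
    """Toy matrix where only ``informative`` columns carry the class signal.

    Labels are the sign of the informative sum, with ambiguous points
    (|sum| < margin) resampled so the two classes separate cleanly.
    """
    rng = np.random.default_rng(seed)
    X = np.empty((0, p))
    y = np.empty(0, dtype=int)
    while len(y) < n:
        cand = rng.normal(size=(n, p))
        s = cand[:, list(informative)].sum(axis=1)
        keep = np.abs(s) > margin
        X = np.vstack([X, cand[keep]])
        y = np.concatenate([y, np.where(s[keep] > 0, 1, -1)])
    return X[:n], y[:n]
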