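import numpy as np
import pytest

from zetamixup import LabeledBatch


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def random_batch_factory(rng):
    """Build small random batches with one-hot labels."""

    def _make(m=4, d=3, k=3, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        feats = r.normal(size=(m, d))
        labels = r.integers(0, k, size=m)
        return LabeledBatch(features=feats, labels=labels, class_count=k)

    return _make
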