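import numpy as np
import pytest

from hlatarget.pipeline import A2_LIKE_ANCHORS, CANONICAL_LENGTH_DIST
from hlatarget.synthetic import make_motif_model, sample_peptides


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def a2_model():
    return make_motif_model("A*02:01", A2_LIKE_ANCHORS, length=9)


@pytest.fixture(scope="session")
def a2_repertoire(a2_model):
    """2,000 peptides from the A2-like planted motif, canonical lengths."""
    return sample_peptides(a2_model, 2000, CANONICAL_LENGTH_DIST, seed=11)
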