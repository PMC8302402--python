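import numpy as np
import pytest

from evoderm import niqe
from evoderm.synthetic_data import LesionImageSpec, make_lesion_image, make_pristine_corpus


@pytest.fixture(scope="session")
def packaged_model():
    """The default pristine NIQE model (fitted once per session)."""
    return niqe.default_model()


@pytest.fixture(scope="session")
def small_model():
    """A small-patch model usable on 96x96 images for fast GA unit tests."""
    corpus = make_pristine_corpus(12, size=96, seed=11)
    return niqe.fit_pristine_model(corpus, patch_size=32)


@pytest.fixture
def lesion_image():
    return make_lesion_image(LesionImageSpec(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
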