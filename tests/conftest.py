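import numpy as np
import pytest

from dcclnet import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    return phantom.PhantomSpec(image_size=32, n_images=20, labeled_fraction=0.3,
                               seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return phantom.make_split(small_spec)


def random_probs(rng, shape):
    """Valid softmax-style probability tensor with the class axis in front."""
    logits = rng.standard_normal(shape)
    e = np.exp(logits - logits.max(axis=0, keepdims=True))
    return e / e.sum(axis=0, keepdims=True)
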