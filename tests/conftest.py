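import numpy as np
import pytest

from mirrorface.synthetic import FaceParams, generate_face


@pytest.fixture(scope="session")
def upright_face():
    """Symmetric, untilted default face: (image, landmarks, ground-truth axis)."""
    return generate_face(FaceParams())


@pytest.fixture(scope="session")
def drooped_face():
    """Face with a left-side droop (image side), ground truth attached."""
    return generate_face(FaceParams(droop_side="left", droop_frac=0.15))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
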