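import numpy as np
import pytest

from cirrus.synthetic import desk_preset, generate_image


@pytest.fixture(scope="session")
def phantom_config():
    return desk_preset(label_artifact_prob=0.0)


@pytest.fixture(scope="session")
def phantom(phantom_config):
    """A textured half-ellipse breast phantom with its truth mask."""
    rng = np.random.default_rng(42)
    image, truth = generate_image(4.0, phantom_config, rng)
    return image, truth


@pytest.fixture(scope="session")
def segmented_phantom(phantom):
    from cirrus.preprocess import segment_breast

    image, truth = phantom
    return image, segment_breast(image)
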