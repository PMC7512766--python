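import numpy as np
import pytest

from oscatt import RunConfig, SceneObject, SceneSpec, make_scene
from oscatt.pipeline import encode_image


@pytest.fixture(scope="session")
def two_region_image():
    """A small two-colour scene: one bright rectangle on a dark background."""
    spec = SceneSpec(
        canvas=(8, 12),
        background=(30, 30, 30),
        objects=(SceneObject("rectangle", (2, 2), (4, 5), (255, 255, 230)),),
    )
    return make_scene(spec)


@pytest.fixture(scope="session")
def two_region_encoded(two_region_image):
    image, labels = two_region_image
    contrast, scene, o_r = encode_image(image, RunConfig())
    return image, labels, contrast, scene, o_r
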