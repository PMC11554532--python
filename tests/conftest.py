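import numpy as np
import pytest

from planefusion.synthetic import (
    ImageSetSpec,
    PlantedFeatureSpec,
    generate_feature_matrix,
    generate_plane_images,
)


@pytest.fixture(scope="session")
def planted300():
    """The standing 300x100 planted-feature recovery conditions."""
    fm, truth = generate_feature_matrix(PlantedFeatureSpec(seed=0))
    return fm, truth


@pytest.fixture(scope="session")
def tiny_image_dir(tmp_path_factory):
    """A small synthetic 4-class image folder (32x32, 10 per class)."""
    root = tmp_path_factory.mktemp("imgs")
    spec = ImageSetSpec(images_per_class=10, image_size=32, seed=0)
    generate_plane_images(spec, root)
    return root


@pytest.fixture
def rng():
    return np.random.default_rng(0)
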