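import numpy as np
import pytest

from riceseg.data import SceneConfig, corpus_statistics, generate_dataset, normalize_images


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_scene_config():
    """Desk-scale scene geometry: 64x64 images with proportionally shrunk shapes."""
    return SceneConfig(
        image_size=(64, 64), grain_count=(8, 18), grain_axes=(3, 7),
        stem_count=(1, 3), stem_length=(20, 60), stem_width=(3, 6),
        branch_count=(1, 2), branch_degree=(2, 3),
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_scene_config):
    """8 synthetic scenes + normalized tensors, shared across tests."""
    images, masks = generate_dataset(8, tiny_scene_config, seed=1)
    mean, std = corpus_statistics(images)
    x = normalize_images(images, mean, std)
    y = np.stack(masks)
    return {"images": images, "masks": masks, "x": x, "y": y,
            "mean": mean, "std": std}
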