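import numpy as np
import pytest

from stainqa.images import Domain, ImageFOV
from stainqa.synthetic import RenderParams, SceneParams, render_pair, sample_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    return sample_scene(SceneParams(size=32, n_nuclei=(5, 5)), seed=7)


@pytest.fixture
def small_pair(small_scene):
    return render_pair(small_scene)


class IdentityTransform:
    """Stub transform: returns its input re-tagged to the target domain."""

    def __init__(self, direction):
        self.direction = direction
        self.model_id = f"identity_{direction}"
        self.calls = 0

    def __call__(self, image):
        self.calls += 1
        px = image.pixels if isinstance(image, ImageFOV) else np.asarray(image)
        from stainqa.staining import Direction
        target = (Domain.STAIN if Direction(self.direction).value == "AF_TO_STAIN"
                  else Domain.AF)
        if target is Domain.STAIN and px.ndim == 2:
            px = np.repeat(px[..., None], 3, axis=-1)
        if target is Domain.AF and px.ndim == 3:
            # channel 0 when all channels agree keeps the stub exactly
            # involutive with the replication stub; mean otherwise
            if np.array_equal(px[..., 0], px[..., 1]) and np.array_equal(
                    px[..., 0], px[..., 2]):
                px = px[..., 0]
            else:
                px = px.mean(axis=-1)
        return ImageFOV(px, target)


@pytest.fixture
def identity_pair():
    from stainqa.staining import Direction
    return (IdentityTransform(Direction.AF_TO_STAIN),
            IdentityTransform(Direction.STAIN_TO_AF))
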