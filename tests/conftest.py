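import numpy as np
import pytest

from gramnet.gramnet_core import one_hot
from gramnet.gramnet_train import CLASSES
from gramnet.phantomgen import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_cfg32():
    return PhantomConfig(image_size=32, tumor_radius=(0.06, 0.12), seed=7)


@pytest.fixture(scope="session")
def phantom_batch32(phantom_cfg32):
    """120 cached 32x32 phantoms: (samples, X (N,32,32,1), y one-hot)."""
    samples = [generate_phantom(phantom_cfg32, i) for i in range(120)]
    x = np.stack([s.image for s in samples])[..., None]
    y = one_hot([s.label for s in samples], CLASSES)
    return samples, x, y


@pytest.fixture(scope="session")
def phantom_cfg64():
    return PhantomConfig(image_size=64, seed=11)


@pytest.fixture(scope="session")
def phantom_batch64(phantom_cfg64):
    """60 cached 64x64 phantoms with liver masks for segmentation tests."""
    samples = [generate_phantom(phantom_cfg64, i) for i in range(60)]
    x = np.stack([s.image for s in samples])[..., None]
    masks = np.stack([s.liver_mask for s in samples]).astype(np.float32)
    return samples, x, masks
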