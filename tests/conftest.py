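import numpy as np
import pytest

from radfuse.synthetic import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small 3-class lesion dataset (32x32) for fast pipeline tests."""
    cfg = SynthConfig(n_classes=3, n_per_class=12, image_size=32,
                      texture_effect=2.0, shape_effect=2.0, context_effect=2.0,
                      redundancy=0.3, seed=11)
    samples, manifest = generate_dataset(cfg)
    images = np.stack([s.image for s in samples])
    masks = np.stack([s.mask for s in samples])
    labels = manifest["label"].to_numpy()
    return images, masks, labels


def finite_difference_grad(f, x, eps=1e-6):
    """Central finite differences of a scalar function of one array."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f(x)
        x[i] = orig - eps
        fm = f(x)
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
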