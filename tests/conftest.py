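import numpy as np
import pytest

from cropseg import synthgen


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_labels():
    cfg = synthgen.MosaicConfig(height=256, width=256, seed=7,
                                plot_size_range=(40, 80))
    return synthgen.generate_field_mosaic(cfg)


@pytest.fixture
def small_scene(small_labels):
    lib = synthgen.default_library(noise_sd=0.01)
    return synthgen.render_reflectance(small_labels, lib, seed=8, mix_width=1)


def finite_diff_grad(f, x, eps=1e-2):
    """Central-difference gradient of scalar f at float32 array x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
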