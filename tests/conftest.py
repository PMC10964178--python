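import numpy as np
import pytest

from octstain.ctgen import GeneratorConfig
from octstain.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest valid generator config, for fast structural unit tests."""
    return GeneratorConfig(in_channels=1, out_channels=3, image_size=16,
                           base_width=4, window_size=2, d_model=12,
                           n_rstb=1, n_stl_per_rstb=2, n_heads=3,
                           mlp_ratio=2.0, scpa_patch=1, scpa_d=12,
                           scpa_depth=1)


@pytest.fixture(scope="session")
def phantom_batch():
    """A dozen labeled 64x64 phantoms, half pathological."""
    samples = []
    for i in range(12):
        pathological = i % 2 == 1
        kind = "none" if not pathological else ("lipid" if i % 4 == 1 else "calcium")
        spec = PhantomSpec(height=64, width=64, pathology_kind=kind,
                           pathology_count=0 if not pathological else 2,
                           labeled=True, seed=100 + i)
        samples.append(generate_phantom(spec))
    return samples
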