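import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_genome():
    """Default toy genome: 100 shared + 50 tether-specific peaks, 60 genes."""
    from tetherscope.simulate import ToyGenomeSpec, generate_toy_genome

    return generate_toy_genome(ToyGenomeSpec(seed=0))


@pytest.fixture()
def disk_image():
    """High-contrast disk (radius 40) on a dark background, no noise."""
    size = 101
    yy, xx = np.mgrid[:size, :size] - 50.0
    mask = xx**2 + yy**2 <= 40.0**2
    px = np.where(mask, 200.0, 10.0)
    from tetherscope.morphometry import NucleusImage

    return NucleusImage(px, pixel_size_um=0.05), mask
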