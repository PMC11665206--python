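import matplotlib
import pytest

matplotlib.use("Agg")

from svef3d.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def uniform_seq():
    """Noise-free uniformly contracting phantom at default resolution."""
    return generate_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def small_cfg():
    """Coarse, fast phantom configuration for structural tests."""
    return PhantomConfig(n_circumferential=24, n_longitudinal=12, n_frames=5)


@pytest.fixture(scope="session")
def small_seq(small_cfg):
    return generate_phantom(small_cfg)
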