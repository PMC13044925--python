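import numpy as np
import pytest

from equitomo.geometry import build_group
from equitomo.phantoms import PhantomSpec, generate_paired_dataset, generate_phantom
from equitomo.simulate import NoiseModel
from equitomo.wedge import TiltScheme, make_wedge_mask


@pytest.fixture(scope="session")
def group():
    return build_group()


@pytest.fixture(scope="session")
def scheme60():
    return TiltScheme(-60.0, 60.0, 3.0)


@pytest.fixture(scope="session")
def smooth_phantom32():
    """Compactly supported smooth random volume, 32^3."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(0)
    n = 32
    v = gaussian_filter(rng.standard_normal((n, n, n)), 2.0)
    z, y, x = np.indices((n, n, n)) - (n - 1) / 2
    r = np.sqrt(z**2 + y**2 + x**2)
    v *= np.exp(-((r / (n / 5)) ** 4))
    return v / np.abs(v).max()


@pytest.fixture(scope="session")
def paired48(scheme60):
    """One 48^3 phantom observed twice through the noisy wedge pipeline."""
    spec = PhantomSpec(shape=(48, 48, 48), seed=0)
    nm = NoiseModel("gaussian", sigma=2.0, seed=100)
    return generate_paired_dataset(spec, scheme60, nm, n=1)[0]


@pytest.fixture(scope="session")
def mask48(scheme60):
    return make_wedge_mask((48, 48, 48), scheme60)
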