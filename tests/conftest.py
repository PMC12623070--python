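import numpy as np
import pytest

from myodyn import synthetic


@pytest.fixture(scope="session")
def phantom():
    return synthetic.make_phantom_geometry((32, 32, 48), (2.3, 2.3, 2.5))


@pytest.fixture(scope="session")
def small_phantom():
    return synthetic.make_phantom_geometry((16, 16, 16), (2.3, 2.3, 2.5))


@pytest.fixture(scope="session")
def uniaxial_model():
    """Contraction-like deformation: +20% along x, -5% transverse."""
    return synthetic.DeformationModel(
        amplitude_tensor=np.diag([0.2, -0.05, -0.05])
    )


def frame_grid(model, n):
    return np.arange(n) * model.cycle_duration / n


@pytest.fixture(scope="session")
def phantom_truth(phantom, uniaxial_model):
    times = frame_grid(uniaxial_model, 32)
    return synthetic.analytic_displacement(phantom, uniaxial_model, times)
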