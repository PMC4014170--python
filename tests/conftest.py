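import numpy as np
import pytest

from brachyfit.geometry import reference_layout
from brachyfit.materials import default_materials, default_spectrum
from brachyfit.pipeline import build_kernel_matrix
from brachyfit.transport import TransportConfig

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def materials():
    return default_materials()


@pytest.fixture(scope="session")
def spectrum():
    return default_spectrum()


@pytest.fixture(scope="session")
def ref_layout():
    return reference_layout()


@pytest.fixture(scope="session")
def kernels_mc():
    """Unit-strength MC kernel matrix at the reference layout.

    4e5 histories per seed: enough to define a well-conditioned forward
    model for the regression and recovery tests (which treat the kernel
    itself as the truth, so its MC noise does not bias them).
    """
    return build_kernel_matrix(
        config=TransportConfig(n_histories=400_000, rng_seed=20140120))
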