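import numpy as np
import pytest

from neurofp.io import default_scheme
from neurofp.phantom import (
    LesionSpec,
    PhantomParams,
    make_cohort,
    make_subject,
    make_tensor_field,
    simulate_signal,
)

SMALL_GRID = (32, 32, 12)


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def small_params():
    return PhantomParams(grid_shape=SMALL_GRID, lesion_radius_mm=5.0)


@pytest.fixture(scope="session")
def noiseless_symmetric(small_params):
    """A lesion-free, noiseless, left-right symmetric subject."""
    return make_subject(1, 1, small_params, seed=7, noiseless=True,
                        keep_tensor_field=True)


@pytest.fixture(scope="session")
def noiseless_acute(small_params):
    """A noiseless subject with one acute (reduced-ADC) lesion."""
    return make_subject(2, 2, small_params, seed=11, noiseless=True,
                        keep_tensor_field=True)


@pytest.fixture(scope="session")
def noiseless_sequela(small_params):
    return make_subject(3, 3, small_params, seed=13, noiseless=True,
                        keep_tensor_field=True)


@pytest.fixture(scope="session")
def cohort19():
    """The default-conditions cohort: 8 normal / 8 acute / 3 sequela with
    2% Rician noise, master seed 42."""
    return make_cohort(8, 8, 3, PhantomParams(), master_seed=42)
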