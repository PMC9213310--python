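import numpy as np
import pytest

from bonesct.phantom import (AcquisitionParams, LesionSpec, PhantomSpec,
                             build_label_map)

#: Compact phantom used throughout the unit tests; large enough to hold the
#: full tissue stack and a lesion, small enough to render in milliseconds.
SMALL_SHAPE = (48, 48, 32)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(shape=SMALL_SHAPE, seed=7)


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(shape=SMALL_SHAPE, seed=7, ct_blur_sigma=0.0)


@pytest.fixture(scope="session")
def small_labels(small_spec):
    return build_label_map(small_spec)


@pytest.fixture(scope="session")
def lesion_spec():
    return PhantomSpec(
        shape=SMALL_SHAPE, seed=7, ct_blur_sigma=0.0,
        lesions=(LesionSpec("osteoblastic", center=(24, 24, 16), radius=5.0,
                            hu_delta=400.0),))


@pytest.fixture
def quiet_acq():
    return AcquisitionParams(noise_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
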