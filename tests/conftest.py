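import numpy as np
import pytest

from cochreg import (
    PhantomSpec,
    PlacementScheme,
    build_centerline,
    make_phantom,
    mean_params,
    place_landmarks,
)


@pytest.fixture(scope="session")
def mean_cochlea():
    return mean_params()


@pytest.fixture(scope="session")
def mean_centerline(mean_cochlea):
    return build_centerline(mean_cochlea)


@pytest.fixture(scope="session")
def mean_landmarks(mean_centerline):
    return place_landmarks(mean_centerline, PlacementScheme(90))


@pytest.fixture
def phantom_factory():
    def factory(seed=0, **kwargs):
        return make_phantom(PhantomSpec(seed=seed, **kwargs))

    return factory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
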