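import os

# The training tests multiply many small matrices; BLAS thread pools add
# overhead without benefit at these sizes, so default to one thread (only
# when the caller has not chosen a value, and before numpy loads BLAS).
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from veus.codec import default_color_bar
from veus.phantom import PhantomParams, generate_dataset


@pytest.fixture(scope="session")
def bar():
    return default_color_bar()


@pytest.fixture(scope="session")
def tiny_params():
    """64x64 phantom geometry used throughout the CPU-scale tests.

    pixel_spacing 0.6 mm/px gives a 38.4 mm field of view, matching the
    default 256-pixel geometry, so depth thresholds keep their meaning.
    """
    return PhantomParams(
        image_size=64,
        pixel_spacing=0.6,
        lesion_axes_range=(4.0, 10.0),
        lesion_depth_range=(8.0, 30.0),
        artifact_prob_deep=0.0,
    )


@pytest.fixture(scope="session")
def deep_params():
    """Geometry forcing every lesion's top edge below the 20 mm threshold."""
    return PhantomParams(
        image_size=64,
        pixel_spacing=0.6,
        lesion_axes_range=(3.0, 6.0),
        lesion_depth_range=(27.0, 33.0),
        artifact_prob_deep=0.0,
    )


@pytest.fixture(scope="session")
def small_cases(tiny_params):
    return generate_dataset(tiny_params, 16, 0.5, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
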