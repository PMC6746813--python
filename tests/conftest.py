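import numpy as np
import pytest

from msim import (
    IlluminationParams,
    Raster2D,
    SampleImage,
    acquire_stack,
    make_otf,
    make_pattern_set,
)

# Commensurate reference acquisition: 48-px grid, stripe period 12 px, so a
# 2*pi/3 phase step is an exact 4-px translation and every closed-form
# identity (stripe cancellation, translation equivalence, uniform coverage)
# holds to machine precision.
COMM_N = 48
COMM_K = 1.0 / 12.0
COMM_CUTOFF = 0.125


@pytest.fixture(scope="session")
def comm_optics():
    return make_otf((COMM_N, COMM_N), COMM_CUTOFF)


@pytest.fixture(scope="session")
def comm_params():
    return IlluminationParams(k_x=COMM_K, k_y=COMM_K)


@pytest.fixture(scope="session")
def comm_patterns(comm_params):
    return make_pattern_set((COMM_N, COMM_N), comm_params)


@pytest.fixture(scope="session")
def point_sample():
    s = np.zeros((COMM_N, COMM_N))
    s[COMM_N // 2, COMM_N // 2] = 1.0
    return SampleImage(Raster2D(s), description="custom")


@pytest.fixture(scope="session")
def blob_sample():
    """Smooth random nonnegative sample, reproducible."""
    rng = np.random.default_rng(7)
    base = rng.random((COMM_N, COMM_N))
    from scipy.ndimage import gaussian_filter

    s = gaussian_filter(base, 2.0)
    s -= s.min()
    return SampleImage(Raster2D(s), description="custom")


@pytest.fixture(scope="session")
def comm_stack(blob_sample, comm_patterns, comm_optics):
    return acquire_stack(blob_sample, comm_patterns, comm_optics, noise=None)
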