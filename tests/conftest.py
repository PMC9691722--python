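import numpy as np
import pytest

from tcrspec.fingerprint import SpecificityFingerprint, build_fingerprint
from tcrspec.synth import LibraryGroundTruth, gen_library


@pytest.fixture(scope="session")
def noise_free_library():
    """Complete synthetic scan library with zero measurement noise."""
    return gen_library(LibraryGroundTruth(seed=11, noise=0.0))


@pytest.fixture(scope="session")
def noisy_library():
    """Synthetic scan library at the default measurement-noise level."""
    return gen_library(LibraryGroundTruth(seed=7))


@pytest.fixture(scope="session")
def fingerprint_noise_free(noise_free_library):
    lib, _ = noise_free_library
    return build_fingerprint(lib)


@pytest.fixture(scope="session")
def fingerprint_noisy(noisy_library):
    lib, _ = noisy_library
    return build_fingerprint(lib)


def make_fingerprint(percent, norm_factor, dg_wt=-6.278):
    """Assemble a SpecificityFingerprint directly from a percent matrix.

    Used for reduced-alphabet and hand-constructed cases where the matrix
    itself is the object under test.
    """
    percent = np.asarray(percent, dtype=float)
    return SpecificityFingerprint(
        percent=percent,
        norm_factor=float(norm_factor),
        dg_wt=dg_wt,
        dg_strongest=-8.0,
        dg_weakest=-2.0,
    )
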