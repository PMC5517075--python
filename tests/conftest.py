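"""Shared fixtures: noiseless and default imaging conditions.

All phantom inputs are generated at test time; no image files are stored.
"""

import pytest

from tracheoquant.phantoms import ImagingParams


@pytest.fixture
def clean_imaging() -> ImagingParams:
    """No PSF, no noise: rendered pixels equal the planted scene."""
    return ImagingParams(
        pixel_size_um=0.1,
        psf_sigma_um=0.0,
        poisson_noise=False,
        read_noise_sigma=0.0,
        seed=0,
    )


@pytest.fixture
def default_imaging() -> ImagingParams:
    """The package's default acquisition model (PSF + shot + read noise)."""
    return ImagingParams(seed=0)
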