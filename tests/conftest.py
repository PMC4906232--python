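import numpy as np
import pytest

from fetquant import phantom


@pytest.fixture(scope="session")
def universal_vois():
    """Default universal tumor (88 mm^3) and background (123 mm^3) VOIs."""
    return phantom.default_universal_vois()


@pytest.fixture(scope="session")
def blurred_phantom():
    """Noiseless blurred phantom: 40 mm^3 tumor, uptake ratio 2."""
    spec = phantom.default_spec(40.0, 2.0, noise_kappa=0.0, seed=11)
    return phantom.generate_brain_phantom(spec)


@pytest.fixture(scope="session")
def unblurred_phantom():
    """Noiseless unblurred phantom: the image equals the truth field."""
    spec = phantom.default_spec(40.0, 2.0, noise_kappa=0.0, seed=11, psf_fwhm=(0.0, 0.0, 0.0))
    return phantom.generate_brain_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-noise blurred phantom (kappa = 0.05)."""
    spec = phantom.default_spec(40.0, 2.0, noise_kappa=0.05, seed=11)
    return phantom.generate_brain_phantom(spec)
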