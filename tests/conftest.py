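import numpy as np
import pytest

from polholo.holography import fourier_demodulate, record_interferograms
from polholo.phantom import ComplexField, generate_bimodal_phantom


def angdiff_pi(a, b):
    """Absolute difference of pi-periodic azimuth angles."""
    return np.abs((a - b + np.pi / 2) % np.pi - np.pi / 2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def smooth_field():
    """Band-limited random complex field, well inside the sideband bandwidth."""
    from scipy.ndimage import gaussian_filter

    r = np.random.default_rng(7)
    m = n = 256

    def smooth(s):
        return gaussian_filter(r.standard_normal((m, n)), s, mode="wrap")

    ux = (1 + 0.3 * smooth(6)) * np.exp(1j * 0.8 * smooth(6))
    uy = (0.7 + 0.3 * smooth(6)) * np.exp(1j * (0.5 + 0.8 * smooth(6)))
    return ComplexField(ux.astype(complex), uy.astype(complex))


@pytest.fixture(scope="session")
def bimodal():
    """One bimodal phase phantom with its holographic reconstruction."""
    bp = generate_bimodal_phantom(5)
    rec = fourier_demodulate(
        record_interferograms(bp.field, ref_amplitude=6.0, carrier=(0.25, 0.25)),
        carrier=(0.25, 0.25),
    )
    return bp, rec
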