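import numpy as np
import pytest

from cmfseg.io_formats import VolumeImage
from cmfseg.phantom import PhantomSpec, generate_case, clean_components


@pytest.fixture(scope="session")
def default_case():
    """One default phantom case, shared across tests (deterministic)."""
    spec = PhantomSpec(seed=1)
    pre, post, gt = generate_case(spec)
    return spec, pre, post, gt


@pytest.fixture(scope="session")
def clean_case():
    """Noise-free phantom building blocks."""
    spec = PhantomSpec(seed=1, noise_sigma=0.0)
    return (spec,) + clean_components(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def smooth_slice():
    """A smooth, structured 2-D test slice (no noise)."""
    yy, xx = np.mgrid[0:128, 0:128]
    return (60.0 + 10.0 * np.sin(2 * np.pi * yy / 32) * np.cos(2 * np.pi * xx / 40))


@pytest.fixture()
def band_limited_slice():
    """Zero-mean random field restricted to the bank's well-covered band."""
    gen = np.random.default_rng(0)
    img = gen.standard_normal((128, 128))
    f = np.fft.fft2(img)
    fy = np.fft.fftfreq(128)[:, None]
    fx = np.fft.fftfreq(128)[None, :]
    r = np.hypot(fy, fx)
    f[(r < 0.03) | (r > 0.16)] = 0
    return np.fft.ifft2(f).real
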