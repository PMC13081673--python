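import numpy as np
import pytest

from iolsim.optics import monofocal_vs_kernel
from iolsim.tfvs import FilterSpec, design_lowpass, smooth_kernel


@pytest.fixture(scope="session")
def kernel():
    """Physical monofocal through-focus kernel (3 mm, 15 cpd, 555 nm)."""
    return monofocal_vs_kernel()


@pytest.fixture(scope="session")
def filter_taps():
    """Kaiser low-pass designed to the default spec at 0.05 D sampling."""
    return design_lowpass(FilterSpec(), 0.05)


@pytest.fixture(scope="session")
def filtered_kernel(kernel):
    """Kernel as seen through the estimation filter."""
    return smooth_kernel(kernel, FilterSpec(), 0.05)


def pupil_autocorrelation_otf(nu, pupil_mm, wavelength_nm, defocus_D, n=401):
    """Independent 2-D grid oracle: real part of the defocused OTF.

    Direct numerical autocorrelation of the (quadratic-phase) pupil on a
    cartesian grid — deliberately distinct from the package's 1-D chord
    reduction.
    """
    lam = wavelength_nm * 1e-9
    p = pupil_mm * 1e-3
    fc = (p / lam) * (np.pi / 180.0)
    s = nu / fc
    if s >= 1.0:
        return 0.0
    w20 = defocus_D * (p / 2.0) ** 2 / 2.0
    a = 2.0 * np.pi * w20 / lam
    xs = np.linspace(-1.5, 1.5, n)
    X, Y = np.meshgrid(xs, xs)
    r1 = (X + s) ** 2 + Y ** 2
    r2 = (X - s) ** 2 + Y ** 2
    p1 = np.where(r1 <= 1.0, np.exp(1j * a * r1), 0.0)
    p2 = np.where(r2 <= 1.0, np.exp(1j * a * r2), 0.0)
    num = np.sum(p1 * np.conj(p2))
    den = np.sum(np.abs(np.where(r1 <= 1.0, 1.0, 0.0)) ** 2)
    return float(np.real(num / den))
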