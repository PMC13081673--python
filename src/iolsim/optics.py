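"""Diffraction-limited optics of a circular pupil.

The incoherent OTF of an aberration-free circular aperture is the
autocorrelation of the pupil; with pure defocus the pupil carries a
quadratic phase and the (real part of the) OTF at a single spatial
frequency traces the through-focus response used as the monofocal
building block of temporal multiplexing.

Defocus of ``Δ`` diopters over a pupil of diameter ``p`` corresponds to a
wavefront sag W20 = Δ·p²/8 at the pupil margin.  The angular cutoff
frequency is ``p/λ`` cycles/radian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "cutoff_frequency",
    "diffraction_limited_mtf",
    "defocused_mtf",
    "MonofocalKernel",
    "monofocal_vs_kernel",
    "gaussian_kernel",
]


def _check_params(pupil_mm: float, wavelength_nm: float) -> None:
    if pupil_mm <= 0 or wavelength_nm <= 0:
        raise ValueError("pupil diameter and wavelength must be positive")


def cutoff_frequency(pupil_mm: float, wavelength_nm: float) -> float:
    """Incoherent cutoff frequency in cycles/degree (≈94.3 cpd at 3 mm, 555 nm)."""
    _check_params(pupil_mm, wavelength_nm)
    return (pupil_mm * 1e-3) / (wavelength_nm * 1e-9) * np.pi / 180.0


def diffraction_limited_mtf(nu, pupil_mm: float = 3.0, wavelength_nm: float = 555.0):
    """Diffraction-limited MTF of a circular aperture at ``nu`` cycles/degree.

    MTF(s) = (2/π)(arccos s − s√(1−s²)) with s = nu / cutoff; 0 beyond cutoff.
    """
    _check_params(pupil_mm, wavelength_nm)
    nu_arr = np.asarray(nu, dtype=float)
    if np.any(nu_arr < 0):
        raise ValueError("spatial frequency must be >= 0")
    s = np.clip(nu_arr / cutoff_frequency(pupil_mm, wavelength_nm), 0.0, 1.0)
    mtf = (2.0 / np.pi) * (np.arccos(s) - s * np.sqrt(1.0 - s * s))
    return float(mtf) if np.isscalar(nu) else mtf


def defocused_mtf(nu: float, pupil_mm: float, wavelength_nm: float, defocus_D,
                  n_quad: int = 2001):
    """Real part of the defocused OTF at ``nu`` cycles/degree.

    Evaluated as the 1-D reduction of the pupil autocorrelation: the two
    sheared pupil copies differ by a phase linear in the shear direction,
    so the 2-D overlap integral collapses to a cosine-weighted chord
    integral.  Negative values (spurious resolution) are preserved here;
    :func:`monofocal_vs_kernel` rectifies them.
    """
    _check_params(pupil_mm, wavelength_nm)
    if nu < 0:
        raise ValueError("spatial frequency must be >= 0")
    lam = wavelength_nm * 1e-9
    p = pupil_mm * 1e-3
    s = nu / cutoff_frequency(pupil_mm, wavelength_nm)
    dvals = np.atleast_1d(np.asarray(defocus_D, dtype=float))
    if s >= 1.0:
        out = np.zeros_like(dvals)
        return float(out[0]) if np.isscalar(defocus_D) else out
    # quadratic-phase coefficient over the unit-radius pupil
    w20 = dvals * (p / 2.0) ** 2 / 2.0
    a_coef = 2.0 * np.pi * w20 / lam
    x = np.linspace(-(1.0 - s), (1.0 - s), n_quad)
    ylim = np.minimum(np.sqrt(np.clip(1.0 - (x + s) ** 2, 0.0, None)),
                      np.sqrt(np.clip(1.0 - (x - s) ** 2, 0.0, None)))
    # phase difference between the sheared copies: 4·A·s·x
    integrand = np.cos(4.0 * np.outer(a_coef, s * x)) * (2.0 * ylim)
    vals = np.trapezoid(integrand, x, axis=1) / np.pi
    return float(vals[0]) if np.isscalar(defocus_D) else vals


@dataclass
class MonofocalKernel:
    """Normalized through-focus response of a single focal state.

    ``offsets`` is a symmetric defocus grid (diopters); ``values`` peak at
    1 at zero offset and are rectified to [0, 1].
    """

    offsets: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.offsets.size != self.values.size:
            raise ValueError("offsets and values must have equal length")
        if not np.allclose(self.offsets, -self.offsets[::-1], atol=1e-9):
            raise ValueError("offset grid must be symmetric about 0")
        if np.any(self.values < 0) or np.any(self.values > 1 + 1e-9):
            raise ValueError("kernel values must lie in [0, 1]")
        if abs(self(0.0) - 1.0) > 1e-6:
            raise ValueError("kernel must equal 1 at zero offset")

    def __call__(self, d) -> np.ndarray:
        """Kernel value at defocus distance ``d`` (0 outside support)."""
        return np.interp(d, self.offsets, self.values, left=0.0, right=0.0)

    @property
    def support(self) -> float:
        return float(self.offsets[-1])


def monofocal_vs_kernel(pupil_mm: float = 3.0, nu: float = 15.0,
                        wavelength_nm: float = 555.0,
                        offsets: np.ndarray | None = None) -> MonofocalKernel:
    """Through-focus visual-Strehl kernel of a diffraction-limited eye.

    The defocused single-frequency MTF, rectified (negative lobes set to
    0) and normalized to a peak of 1 at best focus.
    """
    if offsets is None:
        offsets = np.arange(-6.0, 6.0 + 1e-9, 0.05)
    offsets = np.asarray(offsets, dtype=float)
    vals = np.clip(defocused_mtf(nu, pupil_mm, wavelength_nm, offsets), 0.0, None)
    peak = vals.max()
    if peak <= 0:
        raise ValueError("degenerate kernel: zero response at all offsets")
    return MonofocalKernel(offsets=offsets, values=vals / peak)


def gaussian_kernel(sigma: float, offsets: np.ndarray | None = None) -> MonofocalKernel:
    """Gaussian alternative kernel with standard deviation ``sigma`` diopters."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if offsets is None:
        offsets = np.arange(-6.0, 6.0 + 1e-9, 0.05)
    offsets = np.asarray(offsets, dtype=float)
    return MonofocalKernel(offsets=offsets, values=np.exp(-0.5 * (offsets / sigma) ** 2))
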