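"""Estimation of the through-focus visual Strehl ratio (TFVS) from
through-focus MTF data.

The chain mirrors how published bench MTF data are turned into the
optical signature a simulated lens must reproduce: normalization by the
diffraction limit, luminous-efficiency weighting of per-wavelength
curves, zero-phase FIR smoothing, and an optional scale change between
the IOL plane and the entrance pupil.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .curves import TFMTFCurve, TFVSCurve
from .optics import MonofocalKernel, diffraction_limited_mtf

__all__ = [
    "FilterSpec",
    "LuminousWeights",
    "design_lowpass",
    "normalize_tfmtf",
    "polychromatic_average",
    "resample_uniform",
    "smooth_to_tfvs",
    "convert_plane",
    "smooth_kernel",
]

DEFAULT_RESAMPLE_STEP = 0.05  # diopters


@dataclass(frozen=True)
class FilterSpec:
    """Single-pass design targets of the smoothing low-pass FIR.

    Frequencies are in cycles per diopter of defocus (D⁻¹).  The filter is
    applied forward-backward (zero phase), which doubles the stopband
    attenuation in the effective response.
    """

    passband_freq: float = 0.05   # D^-1
    stopband_freq: float = 0.5    # D^-1
    passband_ripple_db: float = 0.05
    stopband_attenuation_db: float = 10.0
    method: str = "kaiser"

    def validate(self, sample_step: float) -> None:
        nyquist = 0.5 / sample_step
        if not (0 < self.passband_freq < self.stopband_freq < nyquist):
            raise ValueError(
                f"need 0 < passband < stopband < Nyquist ({nyquist:g} D^-1)")
        if self.method != "kaiser":
            raise ValueError("only the Kaiser-window design method is supported")


@dataclass(frozen=True)
class LuminousWeights:
    """Luminous-efficiency weights for red/green/blue bench wavelengths."""

    red: float = 0.11
    green: float = 0.99
    blue: float = 0.15

    def __post_init__(self) -> None:
        if min(self.red, self.green, self.blue) <= 0:
            raise ValueError("weights must be positive")

    def for_wavelength(self, wavelength_nm: float) -> float:
        if wavelength_nm >= 600.0:
            return self.red
        if wavelength_nm >= 500.0:
            return self.green
        return self.blue


def design_lowpass(spec: FilterSpec, sample_step: float = DEFAULT_RESAMPLE_STEP,
                   max_taps: int = 4001) -> np.ndarray:
    """Design a Kaiser-window low-pass FIR meeting ``spec`` single-pass.

    The Kaiser method admits one deviation, so the more stringent of the
    passband and stopband requirements governs the window.  The predicted
    tap count can leave the response marginally outside the passband
    bound, so the design is verified with a frequency sweep and lengthened
    until compliant.
    """
    spec.validate(sample_step)
    fs = 1.0 / sample_step
    rp = spec.passband_ripple_db
    delta_p = (10 ** (rp / 20.0) - 1.0) / (10 ** (rp / 20.0) + 1.0)
    delta_s = 10 ** (-spec.stopband_attenuation_db / 20.0)
    atten = -20.0 * np.log10(min(delta_p, delta_s))
    width = spec.stopband_freq - spec.passband_freq
    numtaps, beta = signal.kaiserord(atten, width / (fs / 2.0))
    numtaps |= 1
    cutoff = 0.5 * (spec.passband_freq + spec.stopband_freq)
    while numtaps <= max_taps:
        taps = signal.firwin(numtaps, cutoff, window=("kaiser", beta), fs=fs)
        w, h = signal.freqz(taps, 1, worN=8192, fs=fs)
        mag = 20.0 * np.log10(np.maximum(np.abs(h), 1e-12))
        pass_ok = np.max(np.abs(mag[w <= spec.passband_freq])) <= rp
        stop_ok = np.max(mag[w >= spec.stopband_freq]) <= -spec.stopband_attenuation_db
        if pass_ok and stop_ok:
            return taps
        numtaps += 2
    raise RuntimeError("filter design did not converge")


def normalize_tfmtf(curve: TFMTFCurve) -> TFMTFCurve:
    """Divide by the diffraction-limited MTF at the curve's frequency.

    Values exceeding 1 after normalization (digitization noise) are
    clipped; the clip count is recorded in ``meta['n_clipped']`` and a
    warning is emitted.
    """
    dl = diffraction_limited_mtf(curve.nu, curve.pupil_diameter, curve.wavelength_nm)
    if dl <= 0:
        raise ValueError(
            f"diffraction limit is 0 at {curve.nu} cpd: normalization degenerate")
    vals = curve.values / dl
    n_clipped = int(np.sum(vals > 1.0))
    if n_clipped:
        warnings.warn(f"{n_clipped} normalized value(s) > 1 clipped to 1",
                      stacklevel=2)
        vals = np.minimum(vals, 1.0)
    meta = dict(curve.meta)
    meta["n_clipped"] = n_clipped
    meta["diffraction_limit"] = dl
    return replace(curve, values=vals, meta=meta)


def polychromatic_average(curves: list[TFMTFCurve],
                          weights: LuminousWeights | None = None) -> TFMTFCurve:
    """Luminous-efficiency-weighted mean of per-wavelength curves.

    Curves are resampled onto the first curve's grid restricted to the
    common support; weights are normalized to sum to 1.  A single curve
    is returned unchanged (weight 1), matching how broadband ("white")
    bench data are handled.
    """
    if not curves:
        raise ValueError("no curves given")
    if len(curves) == 1:
        return curves[0]
    nu0, pup0 = curves[0].nu, curves[0].pupil_diameter
    for c in curves[1:]:
        if c.nu != nu0 or c.pupil_diameter != pup0:
            raise ValueError("curves must share spatial frequency and pupil")
    weights = weights or LuminousWeights()
    lo = max(c.defocus[0] for c in curves)
    hi = min(c.defocus[-1] for c in curves)
    if hi <= lo:
        raise ValueError("curves have disjoint defocus grids")
    m = (curves[0].defocus >= lo - 1e-9) & (curves[0].defocus <= hi + 1e-9)
    grid = curves[0].defocus[m]
    if grid.size < 2:
        raise ValueError("common support has fewer than 2 samples")
    wsum = 0.0
    acc = np.zeros_like(grid)
    for c in curves:
        w = weights.for_wavelength(c.wavelength_nm)
        acc += w * c.resample(grid).values
        wsum += w
    return TFMTFCurve(grid, acc / wsum, nu=nu0, wavelength="white",
                      pupil_diameter=pup0)


def resample_uniform(curve: TFMTFCurve,
                     step: float = DEFAULT_RESAMPLE_STEP) -> TFMTFCurve:
    """Linear interpolation onto a uniform grid with the given step."""
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(np.floor((curve.defocus[-1] - curve.defocus[0]) / step + 1e-9))
    grid = curve.defocus[0] + step * np.arange(n + 1)
    return curve.resample(grid)


def _zero_phase(taps: np.ndarray, values: np.ndarray) -> np.ndarray:
    ntaps = taps.size
    n = values.size
    if n < ntaps:
        raise ValueError(
            f"insufficient support: {n} samples < filter length {ntaps}")
    padlen = min(3 * ntaps, n - 1)
    return signal.filtfilt(taps, 1.0, values, padlen=padlen, padtype="even")


def smooth_to_tfvs(curve: TFMTFCurve, spec: FilterSpec | None = None,
                   resample_step: float = DEFAULT_RESAMPLE_STEP) -> TFVSCurve:
    """Zero-phase smoothing of a normalized TF-MTF into the estimated TFVS.

    The curve is resampled onto a uniform grid, then filtered
    forward-backward with the Kaiser FIR designed to ``spec`` (reflection
    padding at the edges).  The output is tagged as the IOL plane.
    """
    spec = spec or FilterSpec()
    uni = resample_uniform(curve, resample_step)
    taps = design_lowpass(spec, resample_step)
    smoothed = _zero_phase(taps, uni.values)
    meta = dict(uni.meta)
    meta["filter_taps"] = taps.size
    return TFVSCurve(uni.defocus, smoothed, plane="IOL", meta=meta)


def convert_plane(curve: TFVSCurve, factor: float = 1.0) -> TFVSCurve:
    """Scale the defocus axis from the IOL plane to the entrance pupil.

    The exact conversion depends on the pseudophakic eye model, so the
    scalar is configurable; the default of 1.0 leaves the axis unchanged.
    The operation is inverted by ``1/factor``.
    """
    if factor <= 0:
        raise ValueError("plane conversion factor must be positive")
    if curve.plane != "IOL":
        raise ValueError("curve is already in the entrance-pupil plane")
    grid = curve.defocus * factor
    return TFVSCurve(grid, curve.values.copy(), plane="entrance_pupil",
                     meta=dict(curve.meta, plane_factor=factor))


def smooth_kernel(kernel: MonofocalKernel, spec: FilterSpec | None = None,
                  sample_step: float = DEFAULT_RESAMPLE_STEP) -> MonofocalKernel:
    """The monofocal kernel as seen through the estimation filter.

    Fitting an estimated (filtered) TFVS with raw kernels compares unlike
    objects; passing the kernel through the same zero-phase filter makes
    the mixture model consistent with the estimation chain and keeps the
    solved profiles sparse.
    """
    spec = spec or FilterSpec()
    step = float(np.diff(kernel.offsets).mean())
    if abs(step - sample_step) > 1e-9:
        grid = np.arange(-kernel.support, kernel.support + 1e-9, sample_step)
        kernel = MonofocalKernel(grid, kernel(grid))
    taps = design_lowpass(spec, sample_step)
    vals = np.clip(_zero_phase(taps, kernel.values), 0.0, None)
    return MonofocalKernel(kernel.offsets, vals / vals.max())
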