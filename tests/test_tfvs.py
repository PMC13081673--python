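import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import lfilter

from iolsim.curves import TFMTFCurve, TFVSCurve
from iolsim.tfvs import (FilterSpec, LuminousWeights, convert_plane,
                         design_lowpass, normalize_tfmtf,
                         polychromatic_average, resample_uniform,
                         smooth_to_tfvs)

GRID = np.round(np.arange(-6.0, 2.0 + 1e-9, 0.05), 10)


def make_curve(values, wavelength=555.0, grid=GRID):
    return TFMTFCurve(grid, values, wavelength=wavelength)


def single_pass_gain(taps, freq, fs=20.0, n=6000):
    """Independent frequency-sweep measurement of the filter magnitude.

    Drives the filter with a long sinusoid and measures the steady-state
    output amplitude — no use of freqz, which the design loop relies on.
    """
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * freq * t)
    y = lfilter(taps, 1.0, x)
    core = slice(len(taps) * 2, n)  # past the transient
    return np.max(np.abs(y[core])) / np.max(np.abs(x[core]))


class TestNormalize:
    def test_value_equal_to_diffraction_limit_maps_to_one(self):
        from iolsim.optics import diffraction_limited_mtf
        dl = diffraction_limited_mtf(15.0, 3.0, 555.0)
        c = normalize_tfmtf(make_curve(np.full(GRID.size, dl)))
        np.testing.assert_allclose(c.values, 1.0, atol=1e-12)

    def test_worked_value(self):
        c = normalize_tfmtf(make_curve(np.full(GRID.size, 0.4)))
        assert c.values[0] == pytest.approx(0.501, abs=0.001)

    def test_all_zero_curve_stays_zero(self):
        c = normalize_tfmtf(make_curve(np.zeros(GRID.size)))
        assert np.all(c.values == 0.0)

    def test_supra_limit_values_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            c = normalize_tfmtf(make_curve(np.full(GRID.size, 0.9)))
        assert np.all(c.values <= 1.0)
        assert c.meta["n_clipped"] == GRID.size

    def test_degenerate_normalization_beyond_cutoff(self):
        c = TFMTFCurve(GRID, np.full(GRID.size, 0.1), nu=120.0)
        with pytest.raises(ValueError, match="degenerate"):
            normalize_tfmtf(c)


class TestPolychromaticAverage:
    def test_identical_curves_unchanged(self):
        vals = 0.3 + 0.1 * np.cos(GRID)
        curves = [make_curve(vals, wl) for wl in (480.0, 546.0, 650.0)]
        avg = polychromatic_average(curves)
        np.testing.assert_allclose(avg.values, vals, atol=1e-12)

    def test_single_curve_identity(self):
        c = make_curve(np.full(GRID.size, 0.25), 546.0)
        assert polychromatic_average([c]) is c

    def test_worked_weighted_mean(self):
        curves = [make_curve(np.full(GRID.size, v), wl)
                  for v, wl in ((0.2, 650.0), (0.5, 546.0), (0.3, 480.0))]
        avg = polychromatic_average(curves)
        assert avg.values[0] == pytest.approx(0.4496, abs=1e-4)

    def test_bounded_by_pointwise_min_max(self):
        rng = np.random.default_rng(0)
        curves = [make_curve(rng.uniform(0, 0.5, GRID.size), wl)
                  for wl in (480.0, 546.0, 650.0)]
        avg = polychromatic_average(curves)
        stack = np.stack([c.values for c in curves])
        assert np.all(avg.values >= stack.min(axis=0) - 1e-12)
        assert np.all(avg.values <= stack.max(axis=0) + 1e-12)

    def test_empty_and_disjoint_errors(self):
        with pytest.raises(ValueError):
            polychromatic_average([])
        a = make_curve(np.full(GRID.size, 0.2), 546.0)
        other = TFMTFCurve(GRID + 100.0, np.full(GRID.size, 0.2),
                           wavelength=480.0)
        with pytest.raises(ValueError, match="disjoint"):
            polychromatic_average([a, other])

    def test_luminous_weights_positive(self):
        with pytest.raises(ValueError):
            LuminousWeights(red=0.0)


class TestFilterDesign:
    def test_single_pass_compliance_by_frequency_sweep(self, filter_taps):
        spec = FilterSpec()
        for f in (0.01, 0.03, 0.05):
            dev_db = abs(20 * np.log10(single_pass_gain(filter_taps, f)))
            assert dev_db <= spec.passband_ripple_db
        for f in (0.5, 0.7, 1.0, 2.0):
            atten_db = -20 * np.log10(single_pass_gain(filter_taps, f))
            assert atten_db >= spec.stopband_attenuation_db

    def test_stopband_edge_attenuated_20db_after_two_passes(self, filter_taps):
        # forward-backward application squares the magnitude response
        g = single_pass_gain(filter_taps, 0.5)
        assert -20 * np.log10(g ** 2) >= 20.0

    def test_invalid_band_ordering(self):
        with pytest.raises(ValueError):
            FilterSpec(passband_freq=0.5, stopband_freq=0.05).validate(0.05)

    def test_stopband_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(stopband_freq=11.0).validate(0.05)


class TestSmoothToTFVS:
    def test_constant_curve_preserved_within_ripple(self):
        out = smooth_to_tfvs(make_curve(np.full(GRID.size, 0.5)))
        np.testing.assert_allclose(out.values, 0.5, rtol=0.006)
        assert out.plane == "IOL"
        assert out.defocus.size == GRID.size

    def test_even_symmetric_input_gives_even_symmetric_output(self):
        vals = 0.4 * np.exp(-0.5 * ((GRID + 2.0) / 0.8) ** 2)
        out = smooth_to_tfvs(make_curve(vals))
        i = int(np.argmin(np.abs(out.defocus + 2.0)))
        m = min(i, out.defocus.size - 1 - i)
        left = out.values[i - m:i]
        right = out.values[i + 1:i + m + 1][::-1]
        np.testing.assert_allclose(left, right, atol=1e-9)

    def test_insufficient_support_error(self):
        short = TFMTFCurve(np.arange(0, 1.0, 0.05), np.full(20, 0.3))
        with pytest.raises(ValueError, match="insufficient support"):
            smooth_to_tfvs(short)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(offset=st.floats(0.0, 0.4))
    def test_commutes_with_constant_offset_within_ripple(self, offset):
        vals = 0.2 + 0.1 * np.cos(GRID * 0.5)
        base = smooth_to_tfvs(make_curve(vals))
        shifted = smooth_to_tfvs(make_curve(vals + offset))
        np.testing.assert_allclose(shifted.values, base.values + offset,
                                   atol=0.006 * (offset + 1.0))

    def test_resample_uniform_step(self):
        irregular = TFMTFCurve(np.array([0.0, 0.2, 0.21, 0.9, 1.7]),
                               np.array([0.1, 0.2, 0.2, 0.3, 0.1]))
        out = resample_uniform(irregular, 0.05)
        assert np.allclose(np.diff(out.defocus), 0.05)


class TestConvertPlane:
    def test_identity_factor(self):
        c = TFVSCurve(GRID, np.abs(np.cos(GRID)), plane="IOL")
        out = convert_plane(c, 1.0)
        np.testing.assert_allclose(out.defocus, GRID)
        assert out.plane == "entrance_pupil"

    def test_peak_moves_with_axis_scaling(self):
        vals = np.exp(-0.5 * ((GRID + 3.0) / 0.4) ** 2)
        c = TFVSCurve(GRID, vals, plane="IOL")
        out = convert_plane(c, 0.75)
        peak = out.defocus[np.argmax(out.values)]
        assert peak == pytest.approx(-2.25, abs=1e-9)

    def test_round_trip(self):
        c = TFVSCurve(GRID, np.abs(np.sin(GRID)) + 0.01, plane="IOL")
        fwd = convert_plane(c, 0.8)
        back = TFVSCurve(fwd.defocus / 0.8, fwd.values, plane="IOL")
        np.testing.assert_allclose(back.defocus, c.defocus, atol=1e-12)

    def test_invalid_factor_and_plane(self):
        c = TFVSCurve(GRID, np.abs(np.cos(GRID)), plane="IOL")
        with pytest.raises(ValueError):
            convert_plane(c, 0.0)
        with pytest.raises(ValueError):
            convert_plane(convert_plane(c, 1.0), 1.0)
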