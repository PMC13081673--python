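import numpy as np
import pytest
from scipy.optimize import lsq_linear

from iolsim.curves import TFVSCurve, compare_curves
from iolsim.multiplexing import (TemporalMultiplexModel, TemporalProfile,
                                 default_addition_grid, reconstruct_tfvs,
                                 solve_temporal_coefficients)

GRID = np.round(np.arange(-4.5, 0.5 + 1e-9, 0.05), 10)


def mixture_target(kernel, weights, additions, grid=GRID):
    vals = np.zeros_like(grid)
    for w, a in zip(weights, additions):
        vals += w * kernel(grid + a)
    return TFVSCurve(grid, vals, plane="IOL")


class TestTemporalProfile:
    def test_invariants(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TemporalProfile(np.array([0.0, 1.0]), np.array([0.6, 0.5]))
        with pytest.raises(ValueError, match="unique"):
            TemporalProfile(np.array([1.0, 1.0]), np.array([0.5, 0.5]))

    def test_sorted_and_dwell_times(self):
        p = TemporalProfile(np.array([3.0, 0.0]), np.array([0.3, 0.7]))
        np.testing.assert_allclose(p.additions, [0.0, 3.0])
        np.testing.assert_allclose(p.dwell_times_ms, [14.0, 6.0])
        assert p.dwell_times_ms.sum() == pytest.approx(p.cycle_ms)

    def test_json_round_trip(self, tmp_path):
        p = TemporalProfile(np.array([0.0, 1.75, 3.5]),
                            np.array([0.5, 0.2, 0.3]),
                            meta={"amplitude": 0.4})
        path = tmp_path / "profile.json"
        p.to_json(path)
        q = TemporalProfile.from_json(path)
        np.testing.assert_allclose(q.additions, p.additions)
        np.testing.assert_allclose(q.dwell_fractions, p.dwell_fractions)
        assert q.amplitude == pytest.approx(0.4)


class TestSolver:
    def test_pure_kernel_gives_single_state_at_zero(self, kernel):
        target = mixture_target(kernel, [1.0], [0.0])
        profile = solve_temporal_coefficients(target, kernel)
        assert profile.n_states == 1
        assert profile.additions[0] == pytest.approx(0.0, abs=1e-9)
        assert profile.dwell_fractions[0] == pytest.approx(1.0)

    def test_planted_two_state_mixture_recovered(self, kernel):
        target = mixture_target(kernel, [0.6, 0.4], [0.0, 2.5])
        profile = solve_temporal_coefficients(target, kernel)
        assert profile.n_states == 2
        np.testing.assert_allclose(profile.additions, [0.0, 2.5], atol=0.05)
        np.testing.assert_allclose(profile.dwell_fractions, [0.6, 0.4],
                                   atol=0.02)

    @pytest.mark.parametrize("weights,adds", [
        ([0.5, 0.3, 0.2], [0.0, 1.75, 3.5]),
        ([0.05, 0.35, 0.25, 0.2, 0.15], [0.0, 0.9, 1.8, 2.7, 3.6]),
    ])
    def test_planted_mixtures_up_to_five_states(self, kernel, weights, adds):
        target = mixture_target(kernel, weights, adds)
        profile = solve_temporal_coefficients(target, kernel)
        assert profile.n_states == len(adds)
        np.testing.assert_allclose(profile.additions, adds, atol=0.05)
        np.testing.assert_allclose(profile.dwell_fractions, weights, atol=0.02)

    def test_qp_oracle_same_residual_and_support(self, kernel):
        """Dense bounded-variable least squares agrees with the NNLS path."""
        adds = np.round(np.arange(0.0, 3.1, 0.5), 10)  # 7 candidates
        grid = np.round(np.arange(-3.5, 0.5 + 1e-9, 0.1), 10)  # 41 samples
        target = mixture_target(kernel, [0.5, 0.3, 0.2], [0.0, 1.5, 3.0],
                                grid=grid)
        model = TemporalMultiplexModel(target, kernel, adds)
        res = model.fit()
        oracle = lsq_linear(model._design, target.values,
                            bounds=(0.0, np.inf), tol=1e-14)
        res_norm = np.linalg.norm(target.values - model._design @ res.coefficients)
        oracle_norm = np.linalg.norm(target.values - model._design @ oracle.x)
        assert abs(res_norm - oracle_norm) < 1e-6
        assert np.array_equal(res.coefficients > 1e-6, oracle.x > 1e-6)

    def test_pruning_never_increases_state_count(self, kernel, filtered_kernel):
        # a smooth target forces real pruning work
        vals = 0.3 * np.exp(-0.5 * ((GRID + 2.0) / 1.2) ** 2)
        target = TFVSCurve(GRID, vals, plane="IOL")
        res = TemporalMultiplexModel(target, filtered_kernel).fit()
        full, _ = __import__("scipy.optimize", fromlist=["nnls"]).nnls(
            res.model._design, target.values)
        assert res.n_states <= int(np.count_nonzero(full > 0))
        assert res.max_prune_cost <= res.model.rmse_step_tol + 1e-12

    def test_amplitude_rescales_reconstruction(self, kernel):
        target = mixture_target(kernel, [0.3, 0.2], [0.0, 2.0])
        profile = solve_temporal_coefficients(target, kernel)
        rec = reconstruct_tfvs(profile, kernel, GRID)
        assert np.sqrt(np.mean((rec.values - target.values) ** 2)) < 0.02

    def test_all_zero_target_rejected(self, kernel):
        with pytest.raises(ValueError, match="zero"):
            TemporalMultiplexModel(TFVSCurve(GRID, np.zeros_like(GRID)), kernel)

    def test_wide_kernel_warns(self):
        from iolsim.optics import gaussian_kernel
        wide = gaussian_kernel(4.0)
        short = TFVSCurve(np.arange(-1.0, 1.01, 0.05),
                          np.exp(-np.arange(-1.0, 1.01, 0.05) ** 2))
        with pytest.warns(UserWarning, match="ill-posed"):
            TemporalMultiplexModel(short, wide)

    def test_summary_mentions_states(self, kernel):
        target = mixture_target(kernel, [0.6, 0.4], [0.0, 2.5])
        res = TemporalMultiplexModel(target, kernel).fit()
        text = res.summary()
        assert "n states" in text and "dwell fraction" in text


class TestReconstruct:
    def test_single_state_is_translated_kernel(self, kernel):
        p = TemporalProfile(np.array([2.0]), np.array([1.0]))
        rec = reconstruct_tfvs(p, kernel, GRID, scale=1.0)
        np.testing.assert_allclose(rec.values, kernel(GRID + 2.0), atol=1e-12)

    def test_linearity_in_dwell_weights(self, kernel):
        p1 = TemporalProfile(np.array([0.0]), np.array([1.0]))
        p2 = TemporalProfile(np.array([2.5]), np.array([1.0]))
        mix = TemporalProfile(np.array([0.0, 2.5]), np.array([0.7, 0.3]))
        r1 = reconstruct_tfvs(p1, kernel, GRID, scale=1.0).values
        r2 = reconstruct_tfvs(p2, kernel, GRID, scale=1.0).values
        rm = reconstruct_tfvs(mix, kernel, GRID, scale=1.0).values
        np.testing.assert_allclose(rm, 0.7 * r1 + 0.3 * r2, atol=1e-12)


class TestCompareCurves:
    def test_identical_curves(self, kernel):
        c = mixture_target(kernel, [0.6, 0.4], [0.0, 2.5])
        rep = compare_curves(c, c)
        assert rep.cross_correlation == pytest.approx(1.0)
        assert rep.rmse == pytest.approx(0.0)
        assert rep.peak_shift == pytest.approx(0.0)

    def test_affine_invariance_of_correlation(self, kernel):
        a = mixture_target(kernel, [0.6, 0.4], [0.0, 2.5])
        b = TFVSCurve(a.defocus, 0.5 * a.values + 0.1, plane="IOL")
        rep = compare_curves(a, b)
        assert rep.cross_correlation == pytest.approx(1.0)

    def test_hand_computed_example(self):
        grid = np.array([0.0, 1.0, 2.0])
        a = TFVSCurve(grid, np.array([0.0, 0.1, 0.2]))
        b = TFVSCurve(grid, np.array([0.1, 0.1, 0.3]))
        rep = compare_curves(a, b)
        assert rep.cross_correlation == pytest.approx(0.8660, abs=1e-4)
        assert rep.rmse == pytest.approx(0.0816, abs=1e-4)

    def test_too_few_points_and_zero_variance(self):
        a = TFVSCurve(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="3 common"):
            compare_curves(a, a)
        flat = TFVSCurve(np.arange(3.0), np.full(3, 0.5))
        bumpy = TFVSCurve(np.arange(3.0), np.array([0.1, 0.5, 0.2]))
        with pytest.raises(ValueError, match="variance"):
            compare_curves(flat, bumpy)

    def test_peak_shift_detects_displaced_peak(self, kernel):
        a = mixture_target(kernel, [1.0], [0.0])
        b = mixture_target(kernel, [1.0], [0.3])
        rep = compare_curves(a, b)
        assert rep.peak_shift == pytest.approx(0.3, abs=0.051)
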