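"""One-tissue compartment model, NEC weights, and the basis-function fitter."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from mbfpet.kinetics import (
    default_k2_grid,
    fit_parametric,
    fit_tac,
    make_basis,
    model_tac,
    nec_weights,
    voi_stats,
)
from mbfpet.timing_io import RB82, Tac, frame_average


class TestModelTac:
    def test_k1_zero_is_pure_blood_mixture(self, aif, rvif, schedule):
        got = model_tac(0.0, 0.5, 0.3, 0.1, aif, rvif, schedule).values
        expected = (
            0.3 * frame_average(aif, schedule).values
            + 0.1 * frame_average(rvif, schedule).values
        )
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_k2_zero_is_cumulative_integral(self, aif, schedule):
        got = model_tac(1.0, 0.0, 0.0, 0.0, aif, None, schedule).values
        # oracle: cumulative trapezoid on a fine grid, then frame means
        dt = 0.001
        t = np.arange(0.0, schedule.total_end_s + dt, dt)
        ca = np.interp(t, aif.time_s, aif.activity, left=0.0)
        ct = 1.05 * (1.0 / 60.0) * cumulative_trapezoid(ca, t, initial=0.0)
        expected = np.array(
            [
                ct[(t >= s) & (t < e)].mean()
                for s, e in zip(schedule.start_s, schedule.end_s)
            ]
        )
        np.testing.assert_allclose(got, expected, rtol=2e-3, atol=1e-4 * expected.max())

    def test_matches_fine_riemann_convolution(self, aif, schedule):
        K1, k2, VA = 0.8, 1.0, 0.3
        got = model_tac(K1, k2, VA, 0.0, aif, None, schedule).values
        dt = 0.001
        t = np.arange(0.0, schedule.total_end_s + dt, dt)
        ca = np.interp(t, aif.time_s, aif.activity, left=0.0)
        e = np.exp(-(k2 / 60.0) * dt)
        acc, ct = 0.0, np.zeros_like(t)
        for i in range(1, t.size):
            acc = acc * e + 0.5 * (ca[i - 1] * e + ca[i]) * dt
            ct[i] = acc
        obs = 1.05 * (1 - VA) * (K1 / 60.0) * ct + VA * ca
        expected = np.array(
            [
                obs[(t >= s) & (t < e_)].mean()
                for s, e_ in zip(schedule.start_s, schedule.end_s)
            ]
        )
        assert np.max(np.abs(got - expected)) / expected.max() < 5e-4

    def test_invalid_parameters_rejected(self, aif, schedule):
        with pytest.raises(ValueError):
            model_tac(-0.1, 1.0, 0.1, 0.0, aif, None, schedule)
        with pytest.raises(ValueError):
            model_tac(0.5, 1.0, 0.6, 0.5, aif, None, schedule)
        with pytest.raises(ValueError):
            model_tac(0.5, 1.0, 0.1, 0.2, aif, None, schedule)  # V_RV without rvif


class TestNecWeights:
    def test_equal_frames_equal_counts_give_equal_weights(self):
        from mbfpet.timing_io import FrameSchedule, TracerConstants

        sched = FrameSchedule(np.arange(0.0, 30.0, 3.0), np.arange(3.0, 33.0, 3.0))
        slow = TracerConstants("slow", 1e-12)  # λ → 0 limit
        w = nec_weights(Tac(sched, np.full(10, 5.0)), slow).w
        np.testing.assert_allclose(w, 1.0)

    def test_scale_invariant_after_normalization(self, schedule, rng):
        c = rng.random(len(schedule)) + 0.1
        w1 = nec_weights(Tac(schedule, c), RB82).w
        w2 = nec_weights(Tac(schedule, 2.0 * c), RB82).w
        np.testing.assert_allclose(w1, w2, rtol=1e-12)

    def test_matches_hand_formula(self, schedule, rng):
        c = rng.random(len(schedule)) + 0.1
        dt = schedule.duration_s
        dcf = np.exp(RB82.decay_constant * schedule.mid_s)
        expected = dt**2 / dcf**2 / (c * dt)
        expected /= expected.mean()
        np.testing.assert_allclose(nec_weights(Tac(schedule, c), RB82).w, expected)

    def test_all_zero_tac_raises(self, schedule):
        with pytest.raises(ValueError):
            nec_weights(Tac(schedule, np.zeros(len(schedule))), RB82)


class TestMakeBasis:
    def test_k2_zero_column_is_cumulative_integral(self, aif, schedule):
        b = make_basis(np.array([0.0]), aif, schedule)[:, 0]
        expected = model_tac(1.0, 0.0, 0.0, 0.0, aif, None, schedule).values / 1.05
        np.testing.assert_allclose(b, expected, rtol=1e-12)

    def test_columns_decrease_with_k2_at_late_frames(self, aif, schedule):
        grid = default_k2_grid(20)
        b = make_basis(grid, aif, schedule)
        assert np.all(np.diff(b[-1, :]) < 0)

    def test_basis_times_k1_reproduces_tissue_term(self, aif, schedule):
        grid = default_k2_grid(10)
        b = make_basis(grid, aif, schedule)
        j = 4
        got = model_tac(0.7, float(grid[j]), 0.0, 0.0, aif, None, schedule).values
        np.testing.assert_allclose(1.05 * 0.7 * b[:, j], got, rtol=1e-10)

    def test_empty_or_unsorted_grid_rejected(self, aif, schedule):
        with pytest.raises(ValueError):
            make_basis(np.array([]), aif, schedule)
        with pytest.raises(ValueError):
            make_basis(np.array([2.0, 1.0]), aif, schedule)


class TestFitTac:
    @pytest.mark.parametrize("on_grid", [True, False])
    def test_noiseless_recovery(self, aif, rvif, schedule, on_grid):
        grid = default_k2_grid()
        k2 = float(grid[40]) if on_grid else 0.731
        truth = dict(K1=0.9, k2=k2, V_A=0.25, V_RV=0.05)
        tac = model_tac(truth["K1"], truth["k2"], truth["V_A"], truth["V_RV"],
                        aif, rvif, schedule)
        w = nec_weights(Tac(schedule, np.maximum(tac.values, 0)), RB82)
        fit = fit_tac(tac, aif, rvif=rvif, weights=w, k2_grid=grid)
        tol = 1e-8 if on_grid else 1e-5
        assert abs(fit.K1 - truth["K1"]) / truth["K1"] < tol
        assert abs(fit.k2 - truth["k2"]) / truth["k2"] < tol
        assert abs(fit.V_A - truth["V_A"]) < tol
        assert abs(fit.V_RV - truth["V_RV"]) < tol
        assert fit.n_params == 4

    def test_pure_blood_voxel_hits_boundary(self, aif, schedule):
        tac = frame_average(aif, schedule)
        fit = fit_tac(tac, aif)
        assert fit.on_boundary
        assert fit.V_A == pytest.approx(1.0, abs=1e-6)
        assert fit.K1 < 0.05

    def test_scale_equivariance(self, aif, schedule):
        tac = model_tac(0.8, 0.4, 0.3, 0.0, aif, None, schedule)
        fit1 = fit_tac(tac, aif)
        big_aif = aif.with_activity(10.0 * aif.activity)
        fit2 = fit_tac(tac.with_values(10.0 * tac.values), big_aif)
        assert fit2.K1 == pytest.approx(fit1.K1, rel=1e-6)
        assert fit2.k2 == pytest.approx(fit1.k2, rel=1e-6)
        assert fit2.V_A == pytest.approx(fit1.V_A, rel=1e-6)

    def test_rv_term_never_increases_wss(self, aif, rvif, schedule, rng):
        tac = model_tac(0.7, 0.3, 0.25, 0.08, aif, rvif, schedule)
        noisy = tac.with_values(tac.values * (1 + 0.05 * rng.standard_normal(32)))
        f3 = fit_tac(noisy, aif)
        f4 = fit_tac(noisy, aif, rvif=rvif)
        assert f4.wss <= f3.wss + 1e-9 * f3.wss

    def test_zero_aif_raises(self, schedule, aif):
        flat = aif.with_activity(np.zeros_like(aif.activity))
        tac = Tac(schedule, np.ones(len(schedule)))
        with pytest.raises(ValueError):
            fit_tac(tac, flat)

    def test_noisy_median_k1_bias_small(self, aif, rvif, schedule):
        """Median K1 over 200 noisy replicate TACs stays within 3 % of truth."""
        tac = model_tac(0.8, 0.2, 0.3, 0.05, aif, rvif, schedule).values
        rng = np.random.default_rng(5)
        dcf = np.exp(RB82.decay_constant * schedule.mid_s)
        var = 0.15**2 * np.maximum(tac, 0) * dcf**2 / schedule.duration_s
        reps = tac[None, :] + rng.standard_normal((200, 32)) * np.sqrt(var)
        image = reps.reshape(200, 1, 1, 32)
        w = nec_weights(Tac(schedule, np.maximum(tac, 0)), RB82)
        maps = fit_parametric(
            image, aif, rvif, np.ones((200, 1, 1), bool), schedule, weights=w
        )
        k1s = maps.K1[~maps.failure]
        assert abs(np.median(k1s) - 0.8) / 0.8 < 0.03


class TestFitParametric:
    def test_single_voxel_matches_fit_tac(self, aif, schedule):
        tac = model_tac(0.6, 0.5, 0.2, 0.0, aif, None, schedule)
        image = tac.values.reshape(1, 1, 1, -1)
        maps = fit_parametric(image, aif, None, np.ones((1, 1, 1), bool), schedule)
        single = fit_tac(tac, aif, refine_iters=40)
        assert maps.K1[0, 0, 0] == pytest.approx(single.K1, rel=1e-9)
        assert maps.k2[0, 0, 0] == pytest.approx(single.k2, rel=1e-9)

    def test_empty_mask_and_shape_mismatch(self, aif, schedule):
        image = np.zeros((2, 2, 2, len(schedule)))
        with pytest.raises(ValueError):
            fit_parametric(image, aif, None, np.zeros((2, 2, 2), bool), schedule)
        with pytest.raises(ValueError):
            fit_parametric(image, aif, None, np.ones((3, 2, 2), bool), schedule)


class TestVoiStats:
    def test_constant_and_two_voxel_examples(self):
        labels = np.array([[1, 1], [0, 1]])
        const = np.full((2, 2), 3.3)
        mean, var, n = voi_stats(const, labels)
        assert mean == pytest.approx(3.3)
        assert var == pytest.approx(0.0, abs=1e-20)
        assert n == 3
        vol = np.array([[0.4, 0.6], [9.9, np.nan]])
        mean, var, n = voi_stats(vol, labels)
        assert mean == pytest.approx(0.5)
        assert var == pytest.approx(0.02)
        assert n == 2

    def test_matches_direct_formula_on_random_map(self, rng):
        vol = rng.random((5, 5, 5))
        labels = (rng.random((5, 5, 5)) > 0.5).astype(int)
        mean, var, n = voi_stats(vol, labels)
        sel = vol[labels == 1]
        assert mean == pytest.approx(sel.mean())
        assert var == pytest.approx(sel.var(ddof=1))
        assert n == sel.size

    def test_exclusions_and_empty_voi(self):
        vol = np.ones((2, 2))
        labels = np.ones((2, 2), int)
        with pytest.raises(ValueError):
            voi_stats(vol, labels, exclude=np.ones((2, 2), bool))
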