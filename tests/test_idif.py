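"""Image-derived input-function extraction and correction models."""

import numpy as np
import pytest
from scipy import special

from mbfpet.idif import (
    apply_scale,
    estimate_reference_tissue,
    extract_voi_tac,
    f_test_nested,
    fit_pvc1,
    fit_pvc2,
    fit_scale_auc,
    fit_scale_wls,
    population_scale_factor,
    voi_voxel_count,
    IFCorrection,
)
from mbfpet.kinetics import model_tac
from mbfpet.timing_io import FrameSchedule, Tac, frame_average


@pytest.fixture(scope="module")
def aif_tac(aif, schedule):
    return frame_average(aif, schedule)


@pytest.fixture(scope="module")
def c_t(aif, schedule):
    # a genuine tissue-shaped reference curve
    return model_tac(0.8, 0.2, 0.0, 0.0, aif, None, schedule)


class TestExtractVoiTac:
    def test_uniform_image(self, schedule):
        vals = np.linspace(1, 32, len(schedule))
        image = np.broadcast_to(vals, (3, 3, 3, len(schedule))).copy()
        labels = np.ones((3, 3, 3), int)
        np.testing.assert_allclose(
            extract_voi_tac(image, labels, schedule).values, vals
        )

    def test_lv_center_voi_recovers_input(self, aif, rvif, schedule):
        from mbfpet.synthetic import LABEL_LV, PhantomSpec, simulate_dynamic_pet

        sim = simulate_dynamic_pet(
            PhantomSpec(shape=(24, 24, 12), psf_sigma_mm=0.0), aif, rvif, schedule
        )
        got = extract_voi_tac(sim.image4d, sim.labels, schedule, LABEL_LV)
        np.testing.assert_allclose(
            got.values, frame_average(aif, schedule).values, rtol=1e-10
        )

    def test_fixed_volume_voi_voxel_count(self):
        assert voi_voxel_count(6.5, (2.036, 2.036, 2.0)) == 784

    def test_empty_voi_raises(self, schedule):
        with pytest.raises(ValueError):
            extract_voi_tac(np.zeros((2, 2, 2, 32)), np.zeros((2, 2, 2), int), schedule)


class TestReferenceTissue:
    def test_recovers_known_tissue_component(self, aif, schedule):
        truth = model_tac(0.8, 0.2, 0.0, 0.0, aif, None, schedule).values
        myo = model_tac(0.8, 0.2, 0.35, 0.0, aif, None, schedule)
        c_t, fit = estimate_reference_tissue(myo, aif)
        assert np.max(np.abs(c_t.values[1:] - truth[1:]) / truth.max()) < 1e-3
        assert fit.n_params == 3

    def test_pure_blood_tac_gives_near_zero_tissue(self, aif, schedule, aif_tac):
        c_t, _ = estimate_reference_tissue(aif_tac, aif)
        assert np.max(c_t.values) < 0.05 * aif_tac.values.max()

    def test_output_never_negative(self, aif, schedule):
        myo = model_tac(0.5, 0.4, 0.2, 0.0, aif, None, schedule)
        c_t, _ = estimate_reference_tissue(myo, aif)
        assert np.all(c_t.values >= 0.0)


class TestPvcModels:
    def test_pvc1_identity_and_constructed_mixture(self, aif_tac, c_t):
        assert fit_pvc1(aif_tac, aif_tac, c_t).beta == pytest.approx(1.0, abs=1e-12)
        mixed = aif_tac.with_values(0.85 * aif_tac.values + 0.15 * c_t.values)
        fit = fit_pvc1(mixed, aif_tac, c_t)
        assert fit.beta == pytest.approx(0.85, abs=1e-10)
        assert fit.in_range

    def test_pvc1_degenerate_design_raises(self, aif_tac):
        with pytest.raises(ValueError):
            fit_pvc1(aif_tac, aif_tac, aif_tac)

    def test_pvc2_recovers_free_mixture(self, aif_tac, c_t):
        lv = aif_tac.with_values(0.8 * aif_tac.values + 0.1 * c_t.values)
        fit = fit_pvc2(lv, aif_tac, c_t)
        assert fit.params[0] == pytest.approx(0.8, abs=1e-10)
        assert fit.params[1] == pytest.approx(0.1, abs=1e-10)
        pure = fit_pvc2(aif_tac, aif_tac, c_t)
        assert pure.params[0] == pytest.approx(1.0, abs=1e-10)
        assert pure.params[1] == pytest.approx(0.0, abs=1e-10)

    def test_pvc2_nests_pvc1(self, aif_tac, c_t, rng):
        noisy = aif_tac.with_values(
            0.85 * aif_tac.values + 0.15 * c_t.values
            + 100.0 * rng.standard_normal(len(aif_tac))
        )
        p1 = fit_pvc1(noisy, aif_tac, c_t)
        # evaluating the 2-parameter model at (β, 1-β) reproduces the 1-par WSS
        resid = noisy.values - (
            p1.beta * aif_tac.values + (1 - p1.beta) * c_t.values
        )
        assert p1.wss == pytest.approx(float(resid @ resid), rel=1e-12)
        p2 = fit_pvc2(noisy, aif_tac, c_t)
        assert p2.wss <= p1.wss + 1e-9


class TestScaleModels:
    def test_wls_scale_recovers_scalar(self, aif_tac):
        lv = aif_tac.with_values(0.9 * aif_tac.values)
        assert fit_scale_wls(lv, aif_tac).beta == pytest.approx(0.9, abs=1e-12)

    def test_wls_scale_hand_example(self):
        sched = FrameSchedule(np.array([0.0, 1.0, 2.0]), np.array([1.0, 2.0, 3.0]))
        lv = Tac(sched, np.array([1.0, 2.0, 3.0]))
        a = Tac(sched, np.array([1.0, 2.0, 2.0]))
        assert fit_scale_wls(lv, a).beta == pytest.approx(11.0 / 9.0)

    def test_wls_scale_is_wss_optimal(self, aif_tac, rng):
        lv = aif_tac.with_values(
            0.9 * aif_tac.values + 200.0 * rng.standard_normal(len(aif_tac))
        )
        best = fit_scale_wls(lv, aif_tac)
        for beta in np.linspace(0.5, 1.5, 101):
            wss = float(np.sum((lv.values - beta * aif_tac.values) ** 2))
            assert best.wss <= wss + 1e-6

    def test_auc_scale_and_correction_factor(self, aif_tac):
        assert fit_scale_auc(aif_tac, aif_tac).beta == pytest.approx(1.0)
        lv = aif_tac.with_values(0.92 * aif_tac.values)
        fit = fit_scale_auc(lv, aif_tac)
        assert fit.beta == pytest.approx(0.92, abs=1e-12)
        assert round(1.0 / fit.beta, 2) == 1.09

    def test_auc_scale_never_beats_wls_scale(self, aif_tac, rng):
        lv = aif_tac.with_values(
            0.85 * aif_tac.values + 300.0 * rng.standard_normal(len(aif_tac))
        )
        assert fit_scale_auc(lv, aif_tac).wss >= fit_scale_wls(lv, aif_tac).wss

    def test_apply_scale_and_idempotence(self, aif_tac):
        assert np.array_equal(apply_scale(aif_tac, 1.0).values, aif_tac.values)
        lv = aif_tac.with_values(0.92 * aif_tac.values)
        factor = 1.0 / fit_scale_auc(lv, aif_tac).beta
        corrected = apply_scale(lv, factor)
        assert fit_scale_auc(corrected, aif_tac).beta == pytest.approx(1.0)
        with pytest.raises(ValueError):
            apply_scale(aif_tac, 0.0)

    def test_population_scale_factor(self):
        assert population_scale_factor(np.array([0.90, 0.94])) == pytest.approx(1.0 / 0.92)


class TestAllEstimatorsConsistentOnExactMixture:
    def test_mutual_consistency(self, aif_tac, c_t):
        beta = 0.87
        lv = aif_tac.with_values(beta * aif_tac.values + (1 - beta) * c_t.values)
        assert fit_pvc1(lv, aif_tac, c_t).beta == pytest.approx(beta, abs=1e-10)
        p2 = fit_pvc2(lv, aif_tac, c_t)
        assert p2.params[0] == pytest.approx(beta, abs=1e-9)
        assert p2.params[1] == pytest.approx(1 - beta, abs=1e-9)
        # the implied scale estimators follow from the construction
        dt = lv.frames.duration_s
        implied_auc = float(np.sum(lv.values * dt) / np.sum(aif_tac.values * dt))
        assert fit_scale_auc(lv, aif_tac).beta == pytest.approx(implied_auc)


class TestFTest:
    def test_equal_wss_gives_f_zero_p_one(self):
        r = IFCorrection("pvc1", (0.9,), 2.0, 1)
        f = IFCorrection("pvc2", (0.9, 0.1), 2.0, 2)
        stat, p = f_test_nested(r, f, 32)
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_arithmetic_example(self):
        r = IFCorrection("pvc1", (0.9,), 2.0, 1)
        f = IFCorrection("pvc2", (0.9, 0.1), 1.0, 2)
        stat, p = f_test_nested(r, f, 32)
        assert stat == pytest.approx(30.0)
        # independent p via the regularized incomplete beta representation
        df1, df2 = 1, 30
        p_beta = special.betainc(df2 / 2.0, df1 / 2.0, df2 / (df2 + df1 * stat))
        assert p == pytest.approx(p_beta, rel=1e-12)

    def test_invalid_nesting_raises(self):
        r = IFCorrection("pvc1", (0.9,), 2.0, 1)
        f = IFCorrection("pvc2", (0.9, 0.1), 1.0, 2)
        with pytest.raises(ValueError):
            f_test_nested(f, r, 32)
        with pytest.raises(ValueError):
            f_test_nested(r, f, 2)
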