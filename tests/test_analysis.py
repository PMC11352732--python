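"""Evaluation pipeline: each operation against an independent brute-force
oracle (normal equations, loop summation, polynomial regression), plus
null-calibration and invariance properties."""

import numpy as np
import pytest
from scipy import stats

from met2star import analysis, fmri_sim, phantom, signal_model as sm

TE = (14.0, 28.0, 42.0)


def _design(n=40, block=10, tr=2.0):
    return fmri_sim.make_block_design(tr, n, block)


class TestDetrend:
    def test_annihilates_quadratic(self):
        t = np.arange(20, dtype=float)
        series = (3 + 2 * t + t**2).reshape(1, 1, 1, 20)
        out = analysis.detrend(series)
        np.testing.assert_allclose(out, series.mean(), atol=1e-9)

    def test_restores_mean(self, rng):
        series = rng.standard_normal((3, 3, 2, 50)) + 7.0
        out = analysis.detrend(series)
        np.testing.assert_allclose(out.mean(axis=-1), series.mean(axis=-1),
                                   atol=1e-10)

    def test_matches_polyfit_oracle(self, rng):
        series = rng.standard_normal((2, 2, 1, 30))
        out = analysis.detrend(series)
        t = np.linspace(-1, 1, 30)
        for i in range(2):
            for j in range(2):
                y = series[i, j, 0]
                coef = np.polynomial.polynomial.polyfit(t, y, 2)
                resid = y - np.polynomial.polynomial.polyval(t, coef)
                np.testing.assert_allclose(out[i, j, 0], resid + y.mean(),
                                           atol=1e-10)

    def test_too_few_volumes_rejected(self):
        with pytest.raises(ValueError):
            analysis.detrend(np.zeros((1, 1, 1, 3)))


class TestSmooth:
    def test_zero_fwhm_identity(self, rng):
        x = rng.standard_normal((8, 8, 3, 2))
        np.testing.assert_array_equal(analysis.smooth(x, 0.0), x)

    def test_constant_volume_unchanged(self):
        x = np.full((10, 10, 4, 1), 3.5)
        np.testing.assert_allclose(analysis.smooth(x, 7.0), x, atol=1e-12)

    def test_impulse_spreads_with_expected_sigma(self):
        # 7 mm FWHM on 3.5 mm voxels -> sigma = 2/2.3548 ~ 0.8493 voxels
        x = np.zeros((33, 33, 1, 1))
        x[16, 16, 0, 0] = 1.0
        out = analysis.smooth(x, 7.0, (3.5, 3.5, 3.5))[:, :, 0, 0]
        sigma_expect = 7.0 / (3.5 * np.sqrt(8 * np.log(2)))
        assert sigma_expect == pytest.approx(0.84932180, abs=1e-6)
        # fit sigma from the second moment of the profile
        idx = np.arange(33) - 16
        prof = out[16]
        sigma_fit = np.sqrt((prof * idx**2).sum() / prof.sum())
        assert sigma_fit == pytest.approx(sigma_expect, rel=0.02)


class TestGLM:
    def test_perfect_fit_reports_sentinel(self):
        d = _design()
        reg = fmri_sim.convolved_regressor(d)
        series = (2.0 * reg + 5.0).reshape(1, 1, 1, d.n_volumes)
        glm = analysis.glm_fit(series, d)
        assert glm.betas["task"][0, 0, 0] == pytest.approx(2.0, abs=1e-10)
        assert glm.betas["constant"][0, 0, 0] == pytest.approx(5.0, abs=1e-10)
        assert glm.tmap[0, 0, 0] == analysis.T_SENTINEL

    def test_betas_match_normal_equations_oracle(self, rng):
        d = _design(20, 5)
        series = rng.standard_normal((2, 3, 1, 20))
        nuis = rng.standard_normal((20, 2))
        glm = analysis.glm_fit(series, d, nuisance=nuis)
        x = np.column_stack([fmri_sim.convolved_regressor(d), nuis, np.ones(20)])
        for i in range(2):
            for j in range(3):
                beta = np.linalg.solve(x.T @ x, x.T @ series[i, j, 0])
                assert glm.betas["task"][i, j, 0] == pytest.approx(beta[0], abs=1e-10)
                assert glm.betas["constant"][i, j, 0] == pytest.approx(beta[-1], abs=1e-10)

    def test_null_calibration_uncorrected_p(self):
        # pure-noise series: two-sided p<0.001 in ~0.1% of voxels
        d = _design(210, 10)
        rng = np.random.default_rng(42)
        series = rng.standard_normal((60, 60, 6, 210))
        glm = analysis.glm_fit(series, d)
        frac = (glm.pmap < 1e-3).mean()  # 21600 voxels
        assert frac == pytest.approx(1e-3, abs=4e-4)

    def test_rank_deficient_design_rejected(self):
        d = _design(20, 5)
        nuis = np.column_stack([np.ones(20), np.ones(20)])  # collinear with constant
        with pytest.raises(ValueError, match="rank-deficient"):
            analysis.glm_fit(np.zeros((1, 1, 1, 20)), d, nuisance=nuis)


class TestTsnr:
    def test_constant_series_flagged_zero(self):
        x = np.full((2, 2, 1, 30), 9.0)
        assert (analysis.tsnr(x) == 0).all()

    def test_iid_normal_monte_carlo(self):
        rng = np.random.default_rng(7)
        x = rng.normal(100.0, 5.0, size=(40, 40, 1, 500))
        est = analysis.tsnr(x)
        assert est.mean() == pytest.approx(20.0, rel=0.05)

    def test_invariant_to_polynomial_trends(self, rng):
        x = rng.normal(50, 2, size=(4, 4, 1, 60))
        t = np.arange(60, dtype=float)
        trended = x + 0.5 * t + 0.01 * t**2
        np.testing.assert_allclose(analysis.tsnr(trended), analysis.tsnr(x),
                                   atol=1e-8)


class TestPsc:
    def test_null_effect_gives_zero_map(self):
        d = _design()
        series = np.full((2, 2, 1, d.n_volumes), 10.0)
        glm = analysis.glm_fit(series, d)
        np.testing.assert_allclose(analysis.psc(glm, d), 0.0, atol=1e-10)

    def test_direct_formula_substitution(self):
        d = _design(210, 10)
        reg = fmri_sim.convolved_regressor(d)
        series = (1.0 * reg + 100.0).reshape(1, 1, 1, 210)
        glm = analysis.glm_fit(series, d)
        out = analysis.psc(glm, d, oversample=16)
        # beta_task=1, beta_const=100 -> PSC = SF * 1 / 100 * 100 = SF
        ref = np.zeros(210)
        ref[10:20] = 1
        ref_d = fmri_sim.TaskDesign(tr_s=2.0, n_volumes=210,
                                    block_len_volumes=10, condition_vector=ref)
        fine = fmri_sim.convolved_regressor(ref_d, oversample=16, normalize="none")
        full = fmri_sim.convolved_regressor(d, oversample=1, normalize="none")
        sf = fine.max() / full.max()
        assert out[0, 0, 0] == pytest.approx(sf, rel=1e-10)
        assert 0.9 < sf < 1.2  # single-block peak on the regressor scale

    def test_invariant_to_global_rescaling(self, rng):
        d = _design(60, 10)
        reg = fmri_sim.convolved_regressor(d)
        series = (rng.normal(100, 1, (3, 3, 1, 60))
                  + 2.0 * reg.reshape(1, 1, 1, 60))
        a = analysis.psc(analysis.glm_fit(series, d), d)
        b = analysis.psc(analysis.glm_fit(series * 10.0, d), d)
        np.testing.assert_allclose(a, b, atol=1e-8)


class TestFunctionalContrast:
    def test_flat_series_zero(self):
        d = _design()
        x = np.full((4, 4, 1, d.n_volumes), 5.0)
        roi = np.ones((4, 4, 1), dtype=bool)
        assert analysis.functional_contrast(x, d, roi) == pytest.approx(0.0, abs=1e-12)

    def test_unit_on_off_difference(self):
        d = _design(210, 10)
        sig = d.condition_vector.astype(float)
        x = np.tile(sig, (4, 4, 1, 1))
        roi = np.ones((4, 4, 1), dtype=bool)
        fc = analysis.functional_contrast(x, d, roi)
        # detrending edge effects only
        assert fc == pytest.approx(1.0, abs=0.05)

    def test_shuffled_labels_average_to_zero(self):
        rng = np.random.default_rng(3)
        d = _design(40, 10)
        x = rng.standard_normal((3, 3, 1, 40))
        roi = np.ones((3, 3, 1), dtype=bool)
        vals = []
        for _ in range(200):
            cond = rng.permutation(d.condition_vector)
            dd = fmri_sim.TaskDesign(tr_s=2.0, n_volumes=40,
                                     block_len_volumes=10, condition_vector=cond)
            vals.append(analysis.functional_contrast(x, dd, roi))
        assert np.mean(vals) == pytest.approx(0.0, abs=0.02)

    def test_empty_roi_rejected(self):
        d = _design()
        with pytest.raises(ValueError):
            analysis.functional_contrast(np.zeros((2, 2, 1, 40)), d,
                                         np.zeros((2, 2, 1), dtype=bool))


class TestUfweMask:
    def _glm_with_t(self, t, dof=30):
        import pandas as pd

        return analysis.GLMResult(betas={}, tmap=t, dof=dof,
                                  design_matrix=pd.DataFrame())

    def test_union_of_one_is_itself(self):
        t = np.zeros((5, 5, 1))
        t[1, 1, 0] = 50.0
        mask = analysis.ufwe_mask([self._glm_with_t(t)], alpha=0.001)
        assert mask.sum() == 1 and mask[1, 1, 0]

    def test_union_of_disjoint_sets_adds(self):
        t1 = np.zeros((10, 10, 1)); t1[:1, :5, 0] = 60.0  # 5 voxels
        t2 = np.zeros((10, 10, 1)); t2[5:, :3, 0] = 60.0  # 15 voxels
        mask = analysis.ufwe_mask([self._glm_with_t(t1), self._glm_with_t(t2)],
                                  alpha=0.001)
        assert mask.sum() == 20

    def test_null_data_rarely_significant(self):
        d = _design(100, 10)
        rng = np.random.default_rng(11)
        empties = 0
        for _ in range(20):
            series = rng.standard_normal((16, 16, 1, 100))
            glm = analysis.glm_fit(series, d)
            if analysis.ufwe_mask([glm], alpha=0.001).sum() == 0:
                empties += 1
        assert empties >= 19

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            analysis.ufwe_mask([self._glm_with_t(np.zeros((2, 2, 1))),
                                self._glm_with_t(np.zeros((3, 3, 1)))])


class TestCompareSeries:
    def test_hand_computed_example(self):
        p, d = analysis.compare_series([1, 2, 3], [2, 4, 6])
        assert d == pytest.approx(2.0)
        assert p == pytest.approx(0.0742, abs=2e-4)
        # cross-check t statistic via scipy directly
        t = stats.ttest_rel([2, 4, 6], [1, 2, 3])
        assert t.statistic == pytest.approx(3.4641016, abs=1e-6)

    def test_identical_samples_degenerate(self):
        with pytest.raises(ValueError):
            analysis.compare_series([1, 2, 3], [1, 2, 3])

    def test_swap_flips_d_keeps_p(self):
        a = [1.0, 2.5, 3.0, 4.2]
        b = [2.0, 2.9, 4.1, 5.0]
        p1, d1 = analysis.compare_series(a, b)
        p2, d2 = analysis.compare_series(b, a)
        assert d1 == pytest.approx(-d2)
        assert p1 == pytest.approx(p2)


class TestMse:
    def test_identical_maps_zero(self):
        x = np.arange(12.0).reshape(3, 4)
        assert analysis.mse(x, x) == 0.0

    def test_constant_offset_squared(self):
        x = np.zeros((5, 5))
        assert analysis.mse(x, x + 3.0) == pytest.approx(9.0)

    def test_matches_loop_oracle(self, rng):
        a = rng.standard_normal((6, 7))
        b = rng.standard_normal((6, 7))
        mask = rng.random((6, 7)) > 0.4
        got = analysis.mse(a, b, mask)
        acc, n = 0.0, 0
        for i in range(6):
            for j in range(7):
                if mask[i, j]:
                    acc += (a[i, j] - b[i, j])**2
                    n += 1
        assert got == pytest.approx(acc / n, abs=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            analysis.mse(np.zeros((2, 2)), np.zeros((2, 2)),
                         np.zeros((2, 2), dtype=bool))


class TestSeriesDerivation:
    def test_llf_series_static_truth_and_oracle(self, rng):
        templates = [phantom.generate_template(64, 64, subject_seed=s)
                     for s in (31, 32)]
        design = _design(8, 2)
        act = np.zeros((64, 64, 2), dtype=bool)
        series = fmri_sim.simulate_series(templates, design, act, 0.0,
                                          te_ms=TE, seed=0)
        derived = analysis.fit_t2star_series(series, "LLF")
        base = np.stack([p.t2star_ms for p in templates], axis=2)
        mask = np.stack([p.mask for p in templates], axis=2)
        for t in range(8):
            np.testing.assert_allclose(derived.data[..., t][mask], base[mask],
                                       rtol=1e-8)
        # per-voxel OLS loop oracle on one random volume
        t = 5
        a = np.column_stack([np.ones(3), -np.asarray(TE)])
        sub = np.argwhere(mask)[rng.integers(0, mask.sum(), 25)]
        for i, j, k in sub:
            y = np.log(series.data[i, j, k, :, t])
            coef = np.linalg.solve(a.T @ a, a.T @ y)
            np.testing.assert_allclose(1 / derived.data[i, j, k, t], coef[1],
                                       atol=1e-10)

    def test_ec_series_static_and_stepwise_oracle(self):
        templates = [phantom.generate_template(64, 64, subject_seed=33)]
        design = fmri_sim.make_block_design(2.0, 4, 2)
        act = np.zeros((64, 64, 1), dtype=bool)
        series = fmri_sim.simulate_series(templates, design, act, 0.0,
                                          te_ms=TE, seed=0)
        t2map = analysis.llf_mean_t2star(series)
        derived = analysis.ec_series(series, t2map)
        # static series: every combined volume identical
        for t in range(1, 4):
            np.testing.assert_allclose(derived.data[..., t], derived.data[..., 0],
                                       atol=1e-12)
        # step-by-step oracle: clip map, Eq-3 weights, loop-weighted sum
        t2c = np.clip(t2map, 1.0, 500.0)
        w = sm.echo_combination_weights(t2c, TE).w
        ref = np.zeros((64, 64, 1))
        for e in range(3):
            ref[..., 0] += w[e, :, :, 0] * series.data[:, :, 0, e, 0].reshape(64, 64)
        np.testing.assert_allclose(derived.data[..., 0], ref, atol=1e-10)
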