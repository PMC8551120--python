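import numpy as np
import pytest
from oracles import pca_scores_eig, svd_pls2_coefficients, vip_by_loops

from rpvolt.chemometrics import (
    CalibrationSet,
    FitMetrics,
    PreprocessSpec,
    compute_metrics,
    fit,
    fit_pcr,
    fit_plsr,
    grid_search_preprocess,
    loadings_correlation,
    predict,
    q2y_loo,
    r2y,
    select_components,
    vip,
)
from rpvolt.errors import InvalidSpecError, NotFittedError


def linear_problem(seed, n=12, p=8, m=2, noise=0.0):
    """Exactly (or nearly) linear Y = X·B + intercept, full-rank X."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    B = rng.normal(size=(p, m))
    Y = X @ B + rng.normal(size=m) + noise * rng.normal(size=(n, m))
    return CalibrationSet(X, Y)


CENTER = PreprocessSpec(center=True)


class TestPlsr:
    def test_exact_linear_data_fully_explained(self):
        cal = linear_problem(0)
        model = fit_plsr(cal, A=8, preprocess=CENTER)
        assert r2y(model, cal.X, cal.Y) == pytest.approx(1.0, abs=1e-8)

    def test_single_informative_feature_dominates_first_weight(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 6))
        Y = np.stack([5.0 * X[:, 3], 5.0 * X[:, 3]], axis=1)
        model = fit_plsr(CalibrationSet(X, Y), A=1, preprocess=CENTER)
        assert int(np.argmax(np.abs(model.W[:, 0]))) == 3

    @pytest.mark.parametrize("seed", range(20))
    def test_coefficients_match_svd_oracle(self, seed):
        cal = linear_problem(seed, n=10, p=6, noise=0.3)
        A = 3
        model = fit_plsr(cal, A, preprocess=CENTER)
        X0 = cal.X - cal.X.mean(axis=0)
        Y0 = cal.Y - cal.Y.mean(axis=0)
        B_ref = svd_pls2_coefficients(X0, Y0, A)
        np.testing.assert_allclose(model.B, B_ref, atol=1e-8)

    def test_predictions_match_sklearn_cross_check(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        import warnings

        for seed in range(5):
            cal = linear_problem(seed, n=14, p=7, noise=0.5)
            model = fit_plsr(cal, A=3, preprocess=CENTER)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # its cap warning, not ours
                sk = sklearn.PLSRegression(
                    n_components=3, scale=False, tol=1e-22, max_iter=200_000
                ).fit(cal.X, cal.Y)
            np.testing.assert_allclose(
                predict(model, cal.X), sk.predict(cal.X), atol=1e-8
            )

    def test_scores_are_orthogonal_and_weights_unit(self):
        cal = linear_problem(2, noise=0.4)
        model = fit_plsr(cal, A=4, preprocess=CENTER)
        G = model.T.T @ model.T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))
        np.testing.assert_allclose(np.linalg.norm(model.W, axis=0), 1.0, atol=1e-12)

    def test_first_weight_is_dominant_singular_vector_of_cross_covariance(self):
        cal = linear_problem(3, noise=0.2)
        model = fit_plsr(cal, A=1, preprocess=CENTER)
        X0 = cal.X - cal.X.mean(axis=0)
        Y0 = cal.Y - cal.Y.mean(axis=0)
        u = np.linalg.svd(X0.T @ Y0)[0][:, 0]
        u *= np.sign(u[np.argmax(np.abs(u))])
        np.testing.assert_allclose(model.W[:, 0], u, atol=1e-8)

    def test_component_count_bounds_enforced(self):
        cal = linear_problem(4)
        with pytest.raises(InvalidSpecError, match="exceeds"):
            fit_plsr(cal, A=cal.n, preprocess=CENTER)

    def test_r2y_monotone_in_components(self):
        cal = linear_problem(5, noise=1.0)
        scores = [
            r2y(fit_plsr(cal, A, CENTER), cal.X, cal.Y) for A in range(1, 8)
        ]
        assert all(b >= a - 1e-10 for a, b in zip(scores, scores[1:]))


class TestPcr:
    def test_full_rank_equals_ordinary_least_squares(self):
        cal = linear_problem(6, n=12, p=5, noise=0.7)
        model = fit_pcr(cal, A=5, preprocess=CENTER)
        X0 = cal.X - cal.X.mean(axis=0)
        Y0 = cal.Y - cal.Y.mean(axis=0)
        B_ols, *_ = np.linalg.lstsq(X0, Y0, rcond=None)
        np.testing.assert_allclose(model.B, B_ols, atol=1e-8)

    def test_response_orthogonal_to_pc1_unexplained(self):
        rng = np.random.default_rng(7)
        t1 = rng.normal(size=40)
        t1 -= t1.mean()
        t2 = rng.normal(size=40)
        t2 -= t2.mean()
        t2 -= (t2 @ t1 / (t1 @ t1)) * t1  # exactly orthogonal to PC1 scores
        X = np.outer(t1, [10.0, 10.0, 0.0]) + np.outer(t2, [0.0, 0.0, 0.1])
        Y = np.stack([t2, -t2], axis=1)  # lives entirely on the tiny PC
        model = fit_pcr(CalibrationSet(X, Y), A=1, preprocess=CENTER)
        assert abs(r2y(model, X, Y)) < 1e-8

    def test_scores_match_eigendecomposition_oracle(self):
        cal = linear_problem(8, n=15, p=6, noise=0.5)
        model = fit_pcr(cal, A=3, preprocess=CENTER)
        X0 = cal.X - cal.X.mean(axis=0)
        np.testing.assert_allclose(model.T, pca_scores_eig(X0, 3), atol=1e-8)


class TestPredict:
    def test_training_predictions_define_r2y(self):
        cal = linear_problem(9, noise=0.5)
        model = fit_plsr(cal, A=3, preprocess=CENTER)
        Y_hat = predict(model, cal.X)
        ss_res = np.sum((cal.Y - Y_hat) ** 2)
        ss_tot = np.sum((cal.Y - cal.Y.mean(axis=0)) ** 2)
        assert r2y(model, cal.X, cal.Y) == pytest.approx(1 - ss_res / ss_tot)

    def test_identical_rows_identical_predictions(self):
        cal = linear_problem(10)
        model = fit_plsr(cal, A=2, preprocess=CENTER)
        X = np.tile(cal.X[0], (4, 1))
        np.testing.assert_allclose(predict(model, X), np.tile(predict(model, X)[0], (4, 1)))

    def test_mean_voltammogram_predicts_mean_concentration(self):
        cal = linear_problem(11, noise=0.3)
        model = fit_plsr(cal, A=3, preprocess=CENTER)
        np.testing.assert_allclose(
            predict(model, cal.X.mean(axis=0)), cal.Y.mean(axis=0), atol=1e-8
        )

    def test_centering_absorbed_into_intercept(self):
        # shifting all inputs by a constant the model saw at train time
        rng = np.random.default_rng(12)
        shift = rng.normal(size=6)
        cal = linear_problem(12, p=6, noise=0.2)
        shifted = CalibrationSet(cal.X + shift, cal.Y)
        m0 = fit_plsr(cal, A=3, preprocess=CENTER)
        m1 = fit_plsr(shifted, A=3, preprocess=CENTER)
        np.testing.assert_allclose(
            predict(m0, cal.X), predict(m1, shifted.X), atol=1e-8
        )

    def test_feature_mismatch_rejected(self):
        cal = linear_problem(13)
        model = fit_plsr(cal, A=2, preprocess=CENTER)
        with pytest.raises(NotFittedError, match="features"):
            predict(model, np.zeros((3, cal.p + 1)))

    def test_negative_predictions_pass_through_unless_clipped(self):
        cal = linear_problem(14, noise=0.1)
        model = fit_plsr(cal, A=2, preprocess=CENTER)
        x = cal.X[0] - 10 * np.abs(cal.X).max()
        raw = predict(model, x)
        clipped = predict(model, x, clip_negative=True)
        assert (clipped >= 0).all()
        assert not np.array_equal(raw, clipped) or (raw >= 0).all()


class TestR2y:
    def test_hand_computed_toy(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        Y = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0], [3.0, 7.0]])
        model = fit_plsr(CalibrationSet(X, Y), A=1, preprocess=CENTER)
        # regression of Y on x: col0 exact; col1 slope 2.3 through centered x
        resid = Y[:, 1] - (Y[:, 1].mean() + 2.3 * (X[:, 0] - 1.5))
        expected = 1 - resid @ resid / float(
            np.sum((Y - Y.mean(axis=0)) ** 2)
        )
        assert r2y(model, X, Y) == pytest.approx(expected, abs=1e-10)

    def test_mean_predictor_scores_zero(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(10, 3))
        Y = rng.normal(size=(10, 2))
        model = fit_plsr(CalibrationSet(X, Y), A=2, preprocess=CENTER)
        # break the coefficients: predict the mean everywhere
        model.B = np.zeros_like(model.B)
        assert r2y(model, X, Y) == pytest.approx(0.0, abs=1e-12)


class TestQ2y:
    def test_matches_explicit_loo_loop(self):
        cal = linear_problem(16, n=9, p=5, noise=0.8)
        spec = PreprocessSpec(center=True, scale_mode="standardize")
        mine = q2y_loo(cal, 2, spec)
        press = 0.0
        for i in range(cal.n):
            keep = np.arange(cal.n) != i
            sub = CalibrationSet(cal.X[keep], cal.Y[keep])
            m = fit(sub, 2, spec, "plsr")
            press += float(np.sum((cal.Y[i] - predict(m, cal.X[i])) ** 2))
        tss = float(np.sum((cal.Y - cal.Y.mean(axis=0)) ** 2))
        assert mine == pytest.approx(1 - press / tss, abs=1e-10)

    def test_generalizes_on_noiseless_linear_data(self):
        cal = linear_problem(17, n=14, p=6)
        assert q2y_loo(cal, 6, CENTER) > 0.99

    def test_pure_noise_response_cross_validates_below_zero(self):
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(100 + seed)
            cal = CalibrationSet(rng.normal(size=(8, 5)), rng.normal(size=(8, 2)))
            vals.append(q2y_loo(cal, 2, CENTER))
        assert np.mean(vals) < 0

    def test_rank_deficient_folds_rejected(self):
        cal = linear_problem(18, n=6, p=8)
        with pytest.raises(InvalidSpecError, match="fold"):
            q2y_loo(cal, 5, CENTER)

    def test_group_level_folds_supported(self):
        cal = linear_problem(19, n=12, p=5, noise=0.5)
        groups = np.repeat(np.arange(4), 3)
        scan = q2y_loo(cal, 2, CENTER)
        grouped = q2y_loo(cal, 2, CENTER, groups=groups)
        assert np.isfinite(grouped) and grouped != scan

    def test_q2y_rarely_exceeds_r2y(self):
        hits = 0
        trials = 40
        for seed in range(trials):
            cal = linear_problem(300 + seed, n=12, p=6, noise=1.0)
            m = fit_plsr(cal, 2, CENTER)
            if q2y_loo(cal, 2, CENTER) <= r2y(m, cal.X, cal.Y) + 0.05:
                hits += 1
        assert hits >= 0.95 * trials


class TestVip:
    def test_equal_weights_give_all_ones(self):
        rng = np.random.default_rng(20)
        t = rng.normal(size=25)
        X = np.outer(t, np.ones(6)) + 1e-9 * rng.normal(size=(25, 6))
        Y = np.stack([t, 2 * t], axis=1)
        model = fit_plsr(CalibrationSet(X, Y), A=1, preprocess=CENTER)
        np.testing.assert_allclose(vip(model).vip, np.ones(6), atol=1e-6)

    @pytest.mark.parametrize("seed,A", [(0, 1), (1, 2), (2, 3), (3, 5)])
    def test_mean_square_is_one(self, seed, A):
        cal = linear_problem(30 + seed, n=12, p=9, noise=0.6)
        model = fit_plsr(cal, A, CENTER)
        prof = vip(model)
        assert np.mean(prof.vip**2) == pytest.approx(1.0, abs=1e-10)
        assert (prof.vip >= 0).all()
        assert prof.n_important == int((prof.vip > 1).sum())

    def test_matches_looped_formula_oracle(self):
        cal = linear_problem(21, n=10, p=5, noise=0.4)
        model = fit_plsr(cal, 3, CENTER)
        np.testing.assert_allclose(
            vip(model).vip, vip_by_loops(model.W, model.Q_load, model.T), atol=1e-10
        )

    def test_pcr_model_unsupported(self):
        cal = linear_problem(22)
        with pytest.raises(NotFittedError, match="PLSR"):
            vip(fit_pcr(cal, 2, CENTER))


class TestLoadingsCorrelation:
    def _block_model(self):
        rng = np.random.default_rng(23)
        n, p = 40, 30
        t1, t2 = rng.normal(size=n), rng.normal(size=n)
        X = np.zeros((n, p))
        X[:, :10] += np.outer(t1, rng.uniform(1, 2, 10))  # analyte-1 block
        X[:, 20:] += np.outer(t2, rng.uniform(1, 2, 10))  # analyte-2 block
        X += 0.01 * rng.normal(size=(n, p))
        Y = np.stack([t1, t2], axis=1)
        return CalibrationSet(X, Y)

    def test_block_structure_maps_to_high_category(self):
        model = fit_plsr(self._block_model(), 2, CENTER)
        shading = loadings_correlation(model, smoothing_window=3)
        high_an1 = np.flatnonzero(shading.category[:, 0] == 2)
        assert len(high_an1) > 0 and (high_an1 < 12).all()
        low_an1 = shading.category[20:, 0]
        assert (low_an1 <= 1).all()

    def test_unit_change_in_y_leaves_categories_invariant(self):
        cal = self._block_model()
        scaled = CalibrationSet(cal.X, cal.Y * 10.0)
        c1 = loadings_correlation(fit_plsr(cal, 2, CENTER), 3).category
        c2 = loadings_correlation(fit_plsr(scaled, 2, CENTER), 3).category
        np.testing.assert_array_equal(c1, c2)

    def test_window_one_uses_raw_magnitudes(self):
        model = fit_plsr(self._block_model(), 2, CENTER)
        s = loadings_correlation(model, smoothing_window=1)
        np.testing.assert_array_equal(s.smoothed, s.raw)


class TestSelectComponents:
    def test_elbow_after_the_large_q2y_jump(self):
        metrics = FitMetrics((2, 3, 4, 5), (0.5, 0.9, 0.91, 0.92), (0.1, 0.6, 0.62, 0.63))
        assert select_components(metrics, "elbow") == 3

    def test_linear_gains_return_largest_with_warning(self):
        metrics = FitMetrics((1, 2, 3, 4), (0.2, 0.4, 0.6, 0.8), (0.1, 0.2, 0.3, 0.4))
        with pytest.warns(UserWarning, match="no elbow"):
            assert select_components(metrics, "elbow") == 4

    def test_fixed_returns_user_choice_with_note(self):
        metrics = FitMetrics((2, 3), (0.5, 0.9), (0.1, 0.6))
        with pytest.warns(UserWarning, match="fixed"):
            assert select_components(metrics, "fixed", fixed=2) == 2

    def test_max_q2y(self):
        metrics = FitMetrics((2, 3, 5), (0.5, 0.9, 0.95), (0.1, 0.6, 0.4))
        assert select_components(metrics, "max_q2y") == 3


class TestGridSearch:
    def test_single_candidate_wins_trivially(self):
        cal = linear_problem(24, noise=0.5)
        best, table = grid_search_preprocess(cal, 2, [CENTER])
        assert best is CENTER and len(table) == 1

    def test_duplicate_candidates_first_wins(self):
        cal = linear_problem(25, noise=0.5)
        a = PreprocessSpec(center=True)
        b = PreprocessSpec(center=True)
        best, _ = grid_search_preprocess(cal, 2, [a, b])
        assert best is a

    def test_standardization_wins_when_scales_hide_information(self):
        rng = np.random.default_rng(26)
        n = 20
        signal = rng.normal(size=n)
        X = np.zeros((n, 6))
        X[:, 0] = 1e4 * rng.normal(size=n)  # loud, useless
        X[:, 1:] = np.outer(signal, np.ones(5)) + 0.05 * rng.normal(size=(n, 5))
        Y = np.stack([signal, -signal], axis=1)
        cal = CalibrationSet(X, Y)
        cands = [CENTER, PreprocessSpec(center=True, scale_mode="standardize")]
        best, table = grid_search_preprocess(cal, 1, cands)
        assert best.scale_mode == "standardize"
        assert table["q2y"].idxmax() == 1


def test_compute_metrics_table_shape(default_calibration, l2_spec):
    fm = compute_metrics(default_calibration, (2, 3), l2_spec)
    assert fm.components == (2, 3)
    assert len(fm.r2y) == len(fm.q2y) == 2
    assert fm.r2y[1] >= fm.r2y[0] - 1e-10
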