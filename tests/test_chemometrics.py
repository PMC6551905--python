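"""PLS1, PCA, grouped cross-validation, factor selection and the
calibration/test split."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as SKPCA

import lipidir as L
from lipidir.chemometrics import CVResult, cross_validate, select_factors
from lipidir.spectra import SpectraError


def _problem(rng, s=20, c=50):
    X = rng.normal(size=(s, c))
    beta = rng.normal(size=c)
    y = X @ beta + rng.normal(scale=0.1, size=s)
    return X, y


class TestPLS1:
    def test_single_orthonormal_component_fits_exactly(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(12, 8))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))  # centred orthonormal columns
        X = Q[:, :5]
        y = 3.0 * X[:, 0]
        model = L.fit_plsr(X, y, n_factors=1)
        _, r2 = L.metrics(y, model.predict(X))
        assert r2 == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_predictions_match_reference_pls_implementation(self, seed):
        rng = np.random.default_rng(seed)
        X, y = _problem(rng)
        for k in (1, 3, 5):
            mine = L.fit_plsr(X, y, n_factors=k).predict(X)
            ref = PLSRegression(n_components=k, scale=False).fit(
                X, y).predict(X).ravel()
            np.testing.assert_allclose(mine, ref, atol=1e-8)

    def test_full_rank_limit_equals_ordinary_least_squares(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 6))
        y = X @ rng.normal(size=6) + rng.normal(scale=0.2, size=30)
        model = L.fit_plsr(X, y, n_factors=6)
        Xd = np.column_stack([np.ones(30), X])
        beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
        np.testing.assert_allclose(model.B, beta[1:], atol=1e-6)

    def test_scores_are_mutually_orthogonal(self):
        rng = np.random.default_rng(1)
        X, y = _problem(rng)
        est = L.PLS1Regression(5).fit(X, y)
        G = est.T_.T @ est.T_
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.diag(G).max()

    def test_training_residual_norm_nonincreasing_in_k(self):
        rng = np.random.default_rng(2)
        X, y = _problem(rng)
        est = L.PLS1Regression(8).fit(X, y)
        res = [np.linalg.norm(y - est.predict(X, k=k)) for k in range(1, 9)]
        assert all(res[i + 1] <= res[i] + 1e-12 for i in range(7))

    def test_zero_variance_response_rejected(self):
        with pytest.raises(SpectraError, match="zero variance"):
            L.fit_plsr(np.eye(4), np.ones(4), n_factors=1)

    def test_rank_exhaustion_warns_and_reduces(self):
        rng = np.random.default_rng(20)
        # 10 samples on an 8-channel grid but only rank-2 structure
        X = np.outer(rng.normal(size=10), rng.normal(size=8)) \
            + np.outer(rng.normal(size=10), rng.normal(size=8))
        y = X @ rng.normal(size=8)
        with pytest.warns(UserWarning, match="rank|degenerate"):
            est = L.PLS1Regression(5).fit(X, y)
        assert est.n_factors_ < 5


class TestPredict:
    def test_in_sample_consistency_at_full_rank(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 4))
        y = X @ rng.normal(size=4) + 1.0
        model = L.fit_plsr(X, y, n_factors=4)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-8)

    def test_mean_input_predicts_mean_response(self):
        rng = np.random.default_rng(4)
        X, y = _problem(rng, s=15, c=10)
        model = L.fit_plsr(X, y, n_factors=3)
        Xm = np.tile(X.mean(axis=0), (4, 1))
        np.testing.assert_allclose(model.predict(Xm), y.mean(), atol=1e-10)

    def test_channel_scaling_invariance(self):
        rng = np.random.default_rng(5)
        X, y = _problem(rng, s=15, c=10)
        model = L.fit_plsr(X, y, n_factors=3)
        X2 = X.copy()
        X2[:, 2] *= 5.0
        model2 = L.PLSModel(
            x_mean=model.x_mean.copy(), y_mean=model.y_mean, W=model.W,
            P=model.P, q=model.q, B=model.B.copy(), n_factors=model.n_factors)
        model2.B[2] /= 5.0
        model2.x_mean[2] *= 5.0
        np.testing.assert_allclose(model2.predict(X2), model.predict(X),
                                   atol=1e-10)

    def test_channel_count_mismatch_raises(self):
        rng = np.random.default_rng(6)
        X, y = _problem(rng, s=10, c=8)
        model = L.fit_plsr(X, y, n_factors=2)
        with pytest.raises(SpectraError, match="channels"):
            model.predict(np.ones((2, 5)))


class TestPCA:
    def test_rank_one_data_explained_by_first_component(self):
        X = np.zeros((2, 5))
        X[1, 2] = 1.0
        res = L.fit_pca(X, 1)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_agrees_with_svd_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 30))
        res = L.fit_pca(X, 5)
        sk = SKPCA(n_components=5).fit(X)
        for k in range(5):
            sign = np.sign(res.loadings[:, k] @ sk.components_[k])
            np.testing.assert_allclose(res.loadings[:, k],
                                       sign * sk.components_[k], atol=1e-8)
        np.testing.assert_allclose(res.explained_variance,
                                   sk.explained_variance_, atol=1e-8)

    def test_duplicated_samples_add_no_new_variance_directions(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(4, 12))
        Xdup = np.vstack([X, X])
        res = L.fit_pca(Xdup, 6)
        assert np.all(res.explained_variance[3:] < 1e-20)

    def test_reconstruction_at_full_rank(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(6, 9))
        res = L.fit_pca(X, 5)
        np.testing.assert_allclose(res.scores @ res.loadings.T,
                                   X - X.mean(axis=0), atol=1e-8)

    def test_too_many_components_rejected(self):
        with pytest.raises(SpectraError):
            L.fit_pca(np.eye(3), 3)


class TestMetrics:
    def test_perfect_and_null_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert L.metrics(y, y) == (0.0, 1.0)
        rmse, r2 = L.metrics(y, np.full(4, y.mean()))
        assert r2 == pytest.approx(0.0)
        assert rmse == pytest.approx(np.sqrt(np.mean((y - y.mean()) ** 2)))

    def test_matches_direct_formula_oracle(self, rng):
        y = rng.normal(size=50)
        yh = rng.normal(size=50)
        rmse, r2 = L.metrics(y, yh)
        assert rmse == pytest.approx(np.sqrt(np.mean((y - yh) ** 2)), abs=1e-12)
        expected_r2 = 1 - np.sum((y - yh) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 == pytest.approx(expected_r2, abs=1e-12)

    def test_zero_variance_response_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            _, r2 = L.metrics(np.ones(5), np.arange(5.0))
        assert np.isnan(r2)


class TestGroupedCV:
    def test_no_group_leaks_into_its_training_fold(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(24, 10))
        y = X @ rng.normal(size=10)
        groups = [i // 3 for i in range(24)]
        cv = cross_validate(X, y, groups, k_max=3)
        # every sample received an out-of-fold prediction
        assert np.isfinite(cv.predictions).all()
        # predictions for a group must be invariant to that group's y-values
        y2 = y.copy()
        y2[:3] += 100.0  # perturb group 0
        cv2 = cross_validate(X, y2, groups, k_max=3)
        np.testing.assert_allclose(cv2.predictions[:3], cv.predictions[:3],
                                   atol=1e-10)

    def test_loo_special_case_matches_brute_force_refit(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(12, 8))
        y = X @ rng.normal(size=8) + rng.normal(scale=0.1, size=12)
        cv = cross_validate(X, y, groups=list(range(12)), k_max=3)
        for i in range(12):
            keep = [j for j in range(12) if j != i]
            est = L.PLS1Regression(3).fit(X[keep], y[keep])
            for k in (1, 2, 3):
                assert cv.predictions[i, k - 1] == pytest.approx(
                    est.predict(X[i:i + 1], k=k)[0], abs=1e-10)

    def test_noiseless_linear_truth_cross_validates_perfectly(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(20, 5))
        w = rng.normal(size=5)
        y = X @ (np.outer(w, w)[:, 0])  # y spanned by a single direction
        y = X @ w
        cv = cross_validate(X, y, groups=list(range(20)), k_max=5)
        assert cv.rmsecv[-1] < 1e-8
        assert cv.r2_cv[-1] == pytest.approx(1.0, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(SpectraError, match="2 distinct groups"):
            cross_validate(np.eye(4), np.arange(4.0), [0, 0, 0, 0], 2)

    def test_k_max_reduced_with_warning_when_folds_are_small(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(6, 10))
        y = rng.normal(size=6)
        with pytest.warns(UserWarning, match="k_max reduced"):
            cv = cross_validate(X, y, groups=[0, 0, 0, 1, 1, 1], k_max=8)
        assert cv.k_max == 2


class TestSelectFactors:
    def _cv(self, rmsecv, fold_rmse=None):
        rmsecv = np.asarray(rmsecv, float)
        if fold_rmse is None:
            fold_rmse = np.tile(rmsecv, (4, 1))
        return CVResult(rmsecv=rmsecv, r2_cv=1 - rmsecv,
                        fold_rmse=np.asarray(fold_rmse, float),
                        predictions=np.empty((0, rmsecv.size)), groups=[],
                        k_max=rmsecv.size)

    def test_min_rule_breaks_ties_toward_fewer_factors(self):
        assert select_factors(self._cv([5, 3, 3, 4]), rule="min") == 2

    def test_min_rule_monotone_curve_picks_k_max(self):
        assert select_factors(self._cv([5, 4, 3, 2, 1]), rule="min") == 5

    def test_one_se_prefers_parsimony_within_one_standard_error(self):
        fold = np.array([[5, 2.5, 2.0, 2.2]] * 2 + [[5, 3.5, 4.0, 4.2]] * 2)
        cv = self._cv([5, 3.0, 2.9, 3.2], fold_rmse=fold)
        # se at k=3 is large enough that k=2 qualifies
        assert select_factors(cv, rule="one_se") == 2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.1, 10), min_size=1, max_size=12))
    def test_one_se_never_exceeds_min_rule(self, curve):
        cv = self._cv(curve)
        assert select_factors(cv, "one_se") <= select_factors(cv, "min")


class TestSplit:
    def _grouped_set(self, n_strains=7, groups_per_strain=10):
        wn = np.arange(4000.0, 3989.0, -2.0)
        metas, rows = [], []
        rng = np.random.default_rng(15)
        ref_rows = []
        for s in range(n_strains):
            for g in range(groups_per_strain):
                strain = f"S{s:02d}"
                sub = "GXMP"[g % 4]
                bio = g // 4 + 1
                metas.append(L.SampleMeta(f"{strain}-{sub}-{bio}", strain,
                                          sub, bio, 1))
                rows.append(rng.normal(size=wn.size))
                ref_rows.append(dict(strain=strain, substrate=sub, bio_rep=bio,
                                     total_lipid=rng.uniform(5, 60),
                                     sat=30.0, mufa=50.0, pufa=10.0))
        sset = L.SpectrumSet(wn, np.vstack(rows), metas)
        return sset, L.ReferenceTable(pd.DataFrame(ref_rows))

    def test_seventy_groups_quarter_fraction_gives_18_test_groups(self):
        sset, ref = self._grouped_set(7, 10)  # 70 groups
        cal, test = L.split_calibration_test(sset, ref, 0.25, seed=0)
        assert len(set(test.groups())) == 18
        assert len(set(cal.groups())) == 52

    def test_same_seed_reproduces_partition(self):
        sset, ref = self._grouped_set()
        a1 = L.split_calibration_test(sset, ref, 0.25, seed=5)
        a2 = L.split_calibration_test(sset, ref, 0.25, seed=5)
        assert a1[1].sample_ids == a2[1].sample_ids

    def test_no_group_straddles_the_split(self, default_sim):
        sset, ref, _ = default_sim
        cal, test = L.split_calibration_test(sset, ref, 0.25, seed=3)
        assert set(cal.groups()).isdisjoint(test.groups())
        assert cal.n_samples + test.n_samples == sset.n_samples


class TestEvaluateRegions:
    def test_seven_preset_rows_for_fatty_acid_response(self, small_sim):
        sset, ref, _ = small_sim
        pre = L.preprocess_strategy(sset, "b")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows = L.evaluate_regions(pre, ref, "sat", seed=0, k_max=6)
        assert list(rows["region"]) == list("abcdefg")
        assert set(rows.columns) == {"region", "rmsecv", "rmse_test", "r2_cv",
                                     "r2_test", "n_factors"}

    def test_zero_noise_lipid_region_calibrates_near_perfectly(self):
        sset, ref, _ = L.simulate_study(seed=21, n_strains=6,
                                        noise=L.NoiseModel.zero())
        pre = L.preprocess_strategy(sset, "a")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows = L.evaluate_regions(pre, ref, "total_lipid", regions=["a"],
                                      seed=0, k_max=8)
        assert rows["r2_test"].iloc[0] >= 0.99

    def test_deterministic_under_fixed_inputs(self, small_sim):
        sset, ref, _ = small_sim
        pre = L.preprocess_strategy(sset, "a")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = L.evaluate_regions(pre, ref, "total_lipid", seed=2, k_max=6)
            r2 = L.evaluate_regions(pre, ref, "total_lipid", seed=2, k_max=6)
        pd.testing.assert_frame_equal(r1, r2)
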