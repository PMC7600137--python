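import numpy as np
import pandas as pd
import pytest

import breathomics as bo
from breathomics import chemometrics as chem
from tests.conftest import two_cluster_data


class TestPcaOutlierScreen:
    def test_displaced_sample_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(scale=0.01, size=(12, 6))
        x[5] += 1.0  # 100 sds away along every axis
        model, flagged = chem.pca_outlier_screen(pd.DataFrame(x), alpha=0.05)
        assert flagged == [5]

    def test_alpha_limits(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.normal(size=(10, 4)))
        _, all_flagged = chem.pca_outlier_screen(x, alpha=1.0)
        assert len(all_flagged) == 10
        _, none_flagged = chem.pca_outlier_screen(x, alpha=0.0)
        assert none_flagged == []

    def test_component_count_bounded_by_rank(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.normal(size=(5, 10)))
        with pytest.raises(ValueError, match="rank"):
            chem.pca_outlier_screen(x, n_components=7)
        with pytest.raises(ValueError, match="3 samples"):
            chem.pca_outlier_screen(x.iloc[:2])

    def test_matches_sklearn_decomposition(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 8)) * np.sqrt([6, 4, 1, 1, 1, 1, 1, 1])
        model, _ = chem.pca_outlier_screen(pd.DataFrame(x), n_components=2)
        sk = PCA(n_components=2).fit(x)
        assert np.allclose(model.explained_variance, sk.explained_variance_)
        assert np.allclose(np.abs(model.loadings), np.abs(sk.components_.T), atol=1e-8)

    def test_loadings_orthonormal_variances_nonincreasing(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.normal(size=(20, 6)))
        model, _ = chem.pca_outlier_screen(x, n_components=3)
        assert np.allclose(model.loadings.T @ model.loadings, np.eye(3), atol=1e-10)
        assert np.all(np.diff(model.explained_variance) <= 1e-12)
        assert (model.t2 >= 0).all() and (model.q >= 0).all()


class TestFitPlsda:
    def test_separated_clusters_training_mcc_one(self):
        x, labels = two_cluster_data(sep=4.0, seed=0)
        model = chem.fit_plsda(x, labels, A=1)
        assert chem.mcc_from_labels(labels, model.predict(x), positive="a") == 1.0

    def test_full_rank_reproduces_ols_fit(self):
        """With A = rank(X), PLS fitted values equal least squares."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 5))
        y = np.where(rng.random(20) > 0.5, 1.0, -1.0)
        y[:2], y[2:4] = 1.0, -1.0  # both classes occupied
        model = chem.fit_plsda(pd.DataFrame(x), np.where(y > 0, "a", "b"), A=5)
        xc = x - x.mean(axis=0)
        yc = model.y_coded - model.y_coded.mean()
        beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
        assert np.allclose(model.decision_function(x),
                           xc @ beta + model.y_mean, atol=1e-6)

    def test_coefficients_collinear_with_sklearn(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(2)
        x = rng.normal(size=(24, 10))
        labels = np.array(["a", "b"] * 12)
        model = chem.fit_plsda(pd.DataFrame(x), labels, A=3)
        y = np.where(labels == model.levels[1], 1.0, -1.0)
        sk = PLSRegression(n_components=3, scale=False).fit(x, y)
        c = np.corrcoef(model.coef, sk.coef_.ravel())[0, 1]
        assert abs(abs(c) - 1.0) < 1e-10

    def test_single_feature_matches_univariate_sign(self):
        rng = np.random.default_rng(3)
        vals = np.r_[rng.normal(2, 1, 10), rng.normal(-2, 1, 10)]
        labels = ["hi"] * 10 + ["lo"] * 10
        model = chem.fit_plsda(pd.DataFrame({"f": vals}), labels, A=1)
        pred = model.predict(vals[:, None])
        centered = vals - vals.mean()
        expected = np.where(
            centered * np.sign(np.cov(centered, model.y_coded)[0, 1]) + model.y_mean >= 0,
            model.levels[1], model.levels[0],
        )
        assert np.array_equal(pred, expected)

    def test_scores_mutually_orthogonal(self):
        x, labels = two_cluster_data(sep=1.0, seed=4)
        model = chem.fit_plsda(x, labels, A=4)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.diag(gram).max()

    def test_degenerate_inputs_rejected(self):
        x, labels = two_cluster_data(seed=5)
        with pytest.raises(ValueError, match="two classes"):
            chem.fit_plsda(x, ["a"] * len(x), A=1)
        with pytest.raises(ValueError, match="A must be"):
            chem.fit_plsda(x, labels, A=len(x))
        with pytest.raises(ValueError, match="variance"):
            chem.fit_plsda(pd.DataFrame(np.ones((10, 3))), ["a"] * 5 + ["b"] * 5, A=1)


class TestVip:
    def test_mean_square_identity(self):
        """sum(VIP^2) = p for any fitted model."""
        for seed in range(5):
            x, labels = two_cluster_data(sep=1.0, p=8, seed=seed)
            model = chem.fit_plsda(x, labels, A=3)
            v = chem.vip(model)
            assert np.isclose((v**2).sum(), 8, rtol=1e-10)

    def test_symmetric_features_equal_vip(self):
        """Identically informative features get identical VIP (A=1)."""
        rng = np.random.default_rng(0)
        signal = np.r_[np.ones(10), -np.ones(10)]
        x = pd.DataFrame({f"f{j}": signal + 0 for j in range(4)})
        model = chem.fit_plsda(x, np.where(signal > 0, "a", "b"), A=1)
        assert np.allclose(chem.vip(model), 1.0)

    def test_informative_feature_attains_max_vip(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.r_[np.ones(15), -np.ones(15)]
            x = rng.normal(size=(30, 20))
            x[:, 7] += 2.0 * y
            model = chem.fit_plsda(pd.DataFrame(x), np.where(y > 0, "a", "b"), A=2)
            hits += chem.vip(model).idxmax() == 7
        assert hits >= 19

    def test_null_response_rejected(self):
        x, labels = two_cluster_data(seed=1)
        model = chem.fit_plsda(x, labels, A=2)
        model.y_loadings = np.zeros_like(model.y_loadings)
        with pytest.raises(ValueError, match="response variance"):
            chem.vip(model)


class TestPostTransform:
    def test_fitted_and_predictions_invariant(self):
        x, labels = two_cluster_data(sep=1.5, p=12, seed=0)
        model = chem.fit_plsda(x, labels, A=3)
        pt = chem.post_transform(model)
        assert np.abs(pt.fitted() - model.fitted()).max() < 1e-10
        assert np.allclose(pt.rotation @ pt.rotation.T, np.eye(3), atol=1e-12)

    def test_orthogonal_scores_uncorrelated_with_response(self):
        x, labels = two_cluster_data(sep=1.0, p=9, seed=1)
        model = chem.fit_plsda(x, labels, A=3)
        pt = chem.post_transform(model)
        yc = model.y_coded - model.y_coded.mean()
        for k in range(pt.orthogonal_scores.shape[1]):
            assert abs(pt.orthogonal_scores[:, k] @ yc) < 1e-8

    def test_predictive_direction_captures_class_orthogonal_captures_noise(self):
        rng = np.random.default_rng(2)
        n = 40
        y = np.r_[np.ones(20), -np.ones(20)]
        noise_factor = rng.normal(size=n)
        x = (
            np.outer(y, rng.normal(size=15)) * 0.8
            + np.outer(noise_factor, rng.normal(size=15)) * 1.2
            + rng.normal(size=(n, 15)) * 0.3
        )
        model = chem.fit_plsda(pd.DataFrame(x), np.where(y > 0, "a", "b"), A=2)
        pt = chem.post_transform(model)
        assert abs(np.corrcoef(pt.predictive_scores, y)[0, 1]) > 0.9
        assert abs(np.corrcoef(pt.orthogonal_scores[:, 0], noise_factor)[0, 1]) > 0.9

    def test_single_component_identity_with_warning(self):
        x, labels = two_cluster_data(seed=3)
        model = chem.fit_plsda(x, labels, A=1)
        with pytest.warns(UserWarning, match="identity"):
            pt = chem.post_transform(model)
        assert np.array_equal(pt.predictive_scores, model.scores[:, 0])

    def test_structured_noise_diagnostic_flags_construction(self):
        rng = np.random.default_rng(4)
        n = 40
        y = np.r_[np.ones(20), -np.ones(20)]
        factor = rng.normal(size=n)
        x = np.outer(y, rng.normal(size=12)) * 0.5 + np.outer(factor, rng.normal(size=12)) * 3.0
        x += rng.normal(size=(n, 12)) * 0.2
        diag = chem.structured_noise_diagnostic(
            pd.DataFrame(x), np.where(y > 0, "a", "b"), A=2, n_perm=30, seed=0
        )
        assert diag["structured_noise_suspected"]
        # negative control: isotropic noise plus class signal only
        rng = np.random.default_rng(0)
        x0 = rng.normal(size=(n, 12)) + np.outer(y, rng.normal(size=12)) * 0.4
        diag0 = chem.structured_noise_diagnostic(
            pd.DataFrame(x0), np.where(y > 0, "a", "b"), A=2, n_perm=30, seed=1
        )
        assert not diag0["structured_noise_suspected"]


class TestMcc:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((10, 10, 0, 0), 1.0),
            ((0, 0, 10, 10), -1.0),
            ((5, 4, 2, 1), 18 / np.sqrt(1260)),
            ((10, 0, 10, 0), 0.0),  # degenerate marginal
        ],
    )
    def test_known_confusions(self, counts, expected):
        assert chem.mcc(*counts) == pytest.approx(expected)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            chem.mcc(-1, 0, 0, 1)
        with pytest.raises(ValueError):
            chem.mcc(0, 0, 0, 0)

    def test_label_interface_matches_counts(self):
        true = np.array([1, 1, 1, 1, 1, 1, -1, -1, -1, -1, -1, -1])
        pred = np.array([1, 1, 1, 1, 1, -1, -1, -1, -1, -1, 1, 1])
        assert chem.mcc_from_labels(true, pred, positive=1) == pytest.approx(
            chem.mcc(5, 4, 2, 1)
        )


class TestCrossValidation:
    def test_separated_classes_mcc_one(self):
        x, labels = two_cluster_data(sep=5.0, seed=0)
        assert chem.cross_validate_mcc(x, labels, A=2, seed=0) == 1.0

    def test_deterministic_under_seed(self):
        x, labels = two_cluster_data(sep=0.5, seed=1)
        a = chem.cross_validate_mcc(x, labels, A=2, seed=5)
        b = chem.cross_validate_mcc(x, labels, A=2, seed=5)
        assert a == b

    def test_noise_centred_near_zero(self):
        rng = np.random.default_rng(2)
        vals = []
        for seed in range(20):
            x = pd.DataFrame(rng.normal(size=(30, 10)))
            labels = np.array(["a", "b"] * 15)
            vals.append(chem.cross_validate_mcc(x, labels, A=2, seed=seed))
        assert abs(np.mean(vals)) < 0.15

    def test_folds_validation(self):
        x, labels = two_cluster_data(seed=3)
        with pytest.raises(ValueError, match="folds"):
            chem.cross_validate_mcc(x, labels, folds=1)


class TestPermutationTest:
    def test_strong_effect_small_p(self):
        x, labels = two_cluster_data(sep=3.0, seed=0)
        res = chem.permutation_test(x, labels, A=2, n_perm=99, seed=0)
        assert res["p_value"] <= 0.05

    def test_observed_below_all_null_gives_p_one(self):
        x, labels = two_cluster_data(sep=0.0, seed=1)
        res = chem.permutation_test(x, labels, A=1, n_perm=50, seed=0, observed=-2.0)
        assert res["p_value"] == 1.0

    def test_add_one_formula_lower_bound(self):
        x, labels = two_cluster_data(sep=5.0, seed=2)
        res = chem.permutation_test(x, labels, A=1, n_perm=19, seed=0)
        assert res["p_value"] >= 1 / 20

    def test_invalid_n_perm(self):
        x, labels = two_cluster_data(seed=3)
        with pytest.raises(ValueError, match="n_perm"):
            chem.permutation_test(x, labels, n_perm=0)


class TestStabilitySelection:
    def test_small_b_deterministic_and_votes_complete(self):
        x, labels = two_cluster_data(sep=1.0, p=6, seed=0)
        a = chem.stability_selection(x, labels, A=1, B=2, n_null=2, seed=3)
        b = chem.stability_selection(x, labels, A=1, B=2, n_null=2, seed=3)
        pd.testing.assert_series_equal(a.selection_frequency, b.selection_frequency)
        assert a.mcc_oob == b.mcc_oob
        voted = a.oob_votes[a.oob_votes["n_oob"] > 0]
        assert voted["predicted"].notna().all()

    def test_frequencies_and_sets_well_formed(self, preprocessed_t0):
        sub, labels, truth, _ = preprocessed_t0
        model = chem.stability_selection(sub, labels, A=2, B=30, n_null=3, seed=0)
        f = model.selection_frequency
        assert ((f >= 0) & (f <= 1)).all()
        assert model.relevant_features <= set(sub.columns)
        assert -1 <= model.mcc_oob <= 1

    def test_planted_features_recovered(self, preprocessed_t0):
        sub, labels, truth, _ = preprocessed_t0
        model = chem.stability_selection(sub, labels, A=2, B=50, n_null=5, seed=1)
        disc = truth.discriminating_feature_ids & set(sub.columns)
        recall = len(model.relevant_features & disc) / len(disc)
        assert recall >= 0.7
        assert model.mcc_oob >= 0.5

    def test_invalid_b(self):
        x, labels = two_cluster_data(seed=1)
        with pytest.raises(ValueError, match="B"):
            chem.stability_selection(x, labels, B=1)

    def test_null_mcc_oob_centred(self):
        """Under the class-exchangeable null, out-of-bag MCC concentrates
        around zero (simulation-calibrated spread)."""
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = pd.DataFrame(rng.normal(size=(42, 40)))
            labels = np.array(["a"] * 26 + ["b"] * 16)
            m = chem.stability_selection(x, labels, A=2, B=50, n_null=1, b_null=2, seed=seed)
            vals.append(m.mcc_oob)
        vals = np.array(vals)
        assert abs(vals.mean()) <= 0.12
        assert np.mean(np.abs(vals) <= 0.35) >= 0.9


class TestMultilevelTransform:
    def make_paired(self, n_subj=8, p=5, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t0 = rng.normal(size=(n_subj, p))
        t1 = t0 + rng.normal(size=(n_subj, p)) * 0.5 + shift
        ids = [f"sub{i}_T0" for i in range(n_subj)] + [f"sub{i}_T1" for i in range(n_subj)]
        table = pd.DataFrame(np.vstack([t0, t1]), index=ids,
                             columns=[f"1.0@{100 + j}.0" for j in range(p)])
        meta = pd.DataFrame({
            "sample_id": ids,
            "subject_id": [f"sub{i}" for i in range(n_subj)] * 2,
            "timepoint": ["T0"] * n_subj + ["T1"] * n_subj,
        })
        return table, meta

    def test_antisymmetry_and_row_count(self):
        table, meta = self.make_paired()
        diffs, labels, groups = chem.multilevel_transform(table, meta)
        assert len(diffs) == 2 * 8
        for subj in groups.unique():
            rows = diffs[groups == subj].to_numpy()
            assert np.allclose(rows[0], -rows[1])
        assert set(labels) == {"+", "-"}

    def test_identical_timepoints_give_zero_matrix_and_no_signal(self):
        table, meta = self.make_paired()
        table.iloc[8:] = table.iloc[:8].to_numpy()  # T1 == T0
        diffs, labels, groups = chem.multilevel_transform(table, meta)
        assert np.allclose(diffs.to_numpy(), 0.0)

    def test_unpaired_subject_rejected(self):
        table, meta = self.make_paired()
        with pytest.raises(ValueError, match="sub3"):
            chem.multilevel_transform(table.drop(index="sub3_T1"),
                                      meta[meta["sample_id"] != "sub3_T1"])

    def test_planted_shift_recovered_by_multilevel_selection(self):
        table, meta = self.make_paired(n_subj=20, p=30, seed=2)
        shifted = list(table.columns[:5])
        table.loc[[f"sub{i}_T1" for i in range(20)], shifted] += 2.0
        diffs, labels, groups = chem.multilevel_transform(table, meta)
        model = chem.stability_selection(
            diffs, labels, A=2, B=50, n_null=5, groups=groups, seed=0
        )
        assert len(model.relevant_features & set(shifted)) >= 4
        assert model.mcc_oob >= 0.8
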