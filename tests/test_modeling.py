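import numpy as np
import pandas as pd
import pytest

from mammotex.modeling import (ModelConfig, ModelingError, TextureRiskModel,
                               augment_baseline, correlation_filter,
                               delong_test, fit_elastic_net_cv, nri, rank_auc,
                               zscore_apply, zscore_fit)


def make_cohort(n=80, p=10, signal=1.5, seed=0):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.4).astype(int)
    X = rng.normal(size=(n, p))
    X[:, 0] += signal * y
    X[:, 1] -= 0.5 * signal * y
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(p)]), y


class TestZScore:
    def test_round_trip(self):
        X = np.random.default_rng(1).normal(3, 5, size=(30, 4))
        mu, sd, keep = zscore_fit(X)
        Z = zscore_apply(X, mu, sd, keep)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-12)

    def test_degenerate_columns_dropped(self):
        X = np.ones((10, 3))
        X[:, 1] = np.arange(10)
        mu, sd, keep = zscore_fit(X)
        assert list(keep) == [False, True, False]


class TestCorrelationFilter:
    def test_exhaustive_small_case(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=100)
        X = pd.DataFrame({
            "wide": base * 10.0,              # corr 1 with 'narrow', bigger IQR
            "narrow": base * 1.0,
            "indep": rng.normal(size=100),
        })
        Xf, removed = correlation_filter(X, 0.9)
        assert removed == ["narrow"]
        assert list(Xf.columns) == ["wide", "indep"]

    def test_iqr_tie_drops_later_column(self):
        base = np.random.default_rng(5).normal(size=60)
        X = pd.DataFrame({"a": base, "b": base.copy()})
        Xf, removed = correlation_filter(X, 0.9)
        assert removed == ["b"]

    def test_no_pairs_above_threshold(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(200, 4)))
        Xf, removed = correlation_filter(X, 0.99)
        assert removed == [] and Xf.shape == X.shape


class TestRankAUC:
    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(7)
        y = (rng.random(200) < 0.3).astype(int)
        p = rng.normal(size=200) + y
        assert rank_auc(p, y) == pytest.approx(roc_auc_score(y, p), abs=1e-10)

    def test_ties_counted_half(self):
        y = np.array([0, 1, 0, 1])
        p = np.array([0.5, 0.5, 0.5, 0.5])
        assert rank_auc(p, y) == pytest.approx(0.5)

    def test_single_class_is_error(self):
        with pytest.raises(ModelingError):
            rank_auc(np.ones(4), np.ones(4))


class TestDeLong:
    def test_against_small_permutation_oracle(self):
        rng = np.random.default_rng(8)
        n = 120
        y = (rng.random(n) < 0.5).astype(int)
        shared = rng.normal(size=n)
        pa = shared + 0.8 * y + rng.normal(size=n)
        pb = shared + 0.3 * y + rng.normal(size=n)
        delta, p = delong_test(pa, pb, y)
        assert delta == pytest.approx(rank_auc(pa, y) - rank_auc(pb, y), abs=1e-12)
        # permutation oracle: swap the two predictors per subject at random
        B = 2000
        null = np.empty(B)
        for k in range(B):
            swap = rng.random(n) < 0.5
            qa = np.where(swap, pb, pa)
            qb = np.where(swap, pa, pb)
            null[k] = rank_auc(qa, y) - rank_auc(qb, y)
        p_perm = (1 + np.sum(np.abs(null) >= abs(delta))) / (B + 1)
        assert p == pytest.approx(p_perm, abs=0.05)

    def test_identical_predictors_p_one(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        p = np.array([0.1, 0.9, 0.2, 0.8, 0.7, 0.3])
        delta, pv = delong_test(p, p.copy(), y)
        assert delta == 0.0 and pv == 1.0

    def test_unpaired_shapes_rejected(self):
        with pytest.raises(ModelingError):
            delong_test(np.ones(4), np.ones(5), np.ones(4))


class TestNRI:
    def test_brute_force_counting(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        new = np.array([0.9, 0.4, 0.5, 0.2, 0.6, 0.3, 0.3, 0.7])
        old = np.array([0.5, 0.6, 0.5, 0.4, 0.2, 0.3, 0.5, 0.6])
        r = nri(new, old, y)
        # cases: up {0, 7}, down {1}, tie {2} -> (2 - 1)/4
        assert r.nri_case_component == pytest.approx((2 - 1) / 4)
        # controls: down {3, 6}, up {4}, tie {5} -> (2 - 1)/4
        assert r.nri_control_component == pytest.approx((2 - 1) / 4)
        assert r.nri_overall == pytest.approx(0.5)

    def test_perfect_improvement(self):
        y = np.array([1, 1, 0, 0])
        r = nri(np.array([0.9, 0.8, 0.1, 0.2]), np.array([0.5, 0.5, 0.5, 0.5]), y)
        assert r.nri_overall == pytest.approx(2.0)


class TestTextureRiskModel:
    def test_separable_signal_high_auc(self, desk_model_config):
        X, y = make_cohort(signal=3.0, seed=11)
        res = TextureRiskModel(X, y, desk_model_config).fit()
        assert res.cv_auc > 0.85
        assert "f0" in res.selected_features
        assert res.auc_ci[0] <= res.cv_auc <= res.auc_ci[1]

    def test_oof_auc_equals_rank_formula(self, desk_model_config):
        X, y = make_cohort(seed=12)
        res = TextureRiskModel(X, y, desk_model_config).fit()
        assert res.cv_auc == pytest.approx(rank_auc(res.oof_pred, y), abs=1e-10)

    def test_every_subject_predicted_once(self, desk_model_config):
        X, y = make_cohort(seed=13)
        res = TextureRiskModel(X, y, desk_model_config).fit()
        assert len(res.oof_pred) == len(y)
        assert res.fold_assignments.max() == desk_model_config.outer_folds - 1

    def test_deterministic(self, desk_model_config):
        X, y = make_cohort(seed=14)
        r1 = TextureRiskModel(X, y, desk_model_config).fit()
        r2 = TextureRiskModel(X, y, desk_model_config).fit()
        np.testing.assert_array_equal(r1.oof_pred, r2.oof_pred)
        assert r1.final_hyperparams == r2.final_hyperparams

    def test_nonbinary_labels_rejected(self, desk_model_config):
        X, y = make_cohort(seed=15)
        with pytest.raises(ModelingError):
            TextureRiskModel(X, y + 1, desk_model_config)

    def test_too_few_cases_rejected(self, desk_model_config):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 3)))
        y = np.zeros(20, int); y[:2] = 1
        with pytest.raises(ModelingError):
            TextureRiskModel(X, y, desk_model_config).fit()

    def test_summary_mentions_auc(self, desk_model_config):
        X, y = make_cohort(seed=16)
        s = TextureRiskModel(X, y, desk_model_config).fit().summary()
        assert "cross-validated AUC" in s

    def test_functional_wrapper(self, desk_model_config):
        X, y = make_cohort(seed=17)
        assert fit_elastic_net_cv(X, y, desk_model_config).cv_auc == \
            TextureRiskModel(X, y, desk_model_config).fit().cv_auc


class TestAugmentBaseline:
    def test_texture_signal_improves_baseline(self, desk_model_config):
        X, y = make_cohort(n=100, signal=2.5, seed=18)
        rng = np.random.default_rng(18)
        cov = pd.DataFrame({"age": rng.normal(55, 10, 100),
                            "bmi": rng.normal(28, 5, 100)})
        out = augment_baseline(cov, X, y, config=desk_model_config)
        assert out["augmented_auc"] > out["baseline_auc"]
        assert out["comparison"].delta_auc == pytest.approx(
            out["augmented_auc"] - out["baseline_auc"], abs=1e-12)

    def test_missing_covariates_dropped_with_warning(self, desk_model_config):
        X, y = make_cohort(n=60, seed=19)
        cov = pd.DataFrame({"age": np.random.default_rng(19).normal(55, 10, 60)})
        cov.iloc[0, 0] = np.nan
        with pytest.warns(UserWarning, match="missing covariates"):
            out = augment_baseline(cov, X, y, config=desk_model_config)
        assert len(out["baseline_oof"]) == 59
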