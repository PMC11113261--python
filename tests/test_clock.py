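import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from nucleoclock.clock import (
    FeatureMatrix,
    auc_mann_whitney,
    build_features,
    classify_age_group,
    evaluate_metrics,
    predict_age,
    stratified_split,
    train_clock,
)
from nucleoclock.io_fragments import SampleMeta
from nucleoclock.simulate import CohortSpec, MixtureLink, generate_subject


def feature_matrix_from(X, kind="size_dist"):
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(
        sample_ids=[f"S{i}" for i in range(X.shape[0])],
        feature_kind=kind,
        X=X,
        grid=np.arange(X.shape[1]),
    )


def perfect_feature_cohort(rng, n=30, n_features=20):
    """Feature 3 equals age exactly; everything else is zero."""
    ages = rng.uniform(20, 90, n)
    X = np.zeros((n, n_features))
    X[:, 3] = ages
    return feature_matrix_from(X), ages


class TestBuildFeatures:
    @staticmethod
    def _samples(ages, seed=0, nf=5_000):
        spec = CohortSpec(
            genome_length=150_000, n_fragments_per_subject=nf, seed=seed
        )
        out = []
        for i, age in enumerate(ages):
            rng = np.random.default_rng(seed * 1000 + i)
            fs, _ = generate_subject(spec, age, rng, f"S{i}")
            out.append((fs, SampleMeta(f"S{i}", age)))
        return out

    def test_size_dist_rows_sum_to_one(self):
        samples = self._samples([30.0, 80.0])
        fm = build_features(samples, "size_dist")
        assert fm.X.shape == (2, 501)
        np.testing.assert_allclose(fm.X.sum(axis=1), 1.0, atol=1e-9)

    def test_same_sample_twice_gives_identical_rows(self):
        samples = self._samples([40.0])
        fs, meta = samples[0]
        fm = build_features(
            [(fs, meta), (fs, SampleMeta("S1b", 40.0))], "distance_autocorr"
        )
        np.testing.assert_array_equal(fm.X[0], fm.X[1])

    def test_distance_autocorr_separates_nrl_groups(self):
        """Rows correlate more within a spacing group than across groups."""
        def cohort(nrl, label, seed):
            spec = CohortSpec(
                genome_length=1_000_000,
                n_fragments_per_subject=50_000,
                nrl_beta0=nrl,
                nrl_beta1=0.0,
                nrl_sigma_subject=0.0,
                seed=seed,
            )
            out = []
            for i in range(3):
                rng = np.random.default_rng(seed * 100 + i)
                fs, _ = generate_subject(spec, 50.0, rng, f"{label}{i}")
                out.append((fs, SampleMeta(f"{label}{i}", 50.0)))
            return out

        fm = build_features(cohort(175.0, "a", 1) + cohort(200.0, "b", 2), "distance_autocorr")
        C = np.corrcoef(fm.X)
        within = np.concatenate([C[:3, :3][np.triu_indices(3, 1)], C[3:, 3:][np.triu_indices(3, 1)]])
        across = C[:3, 3:].ravel()
        assert within.mean() > across.mean()

    def test_empty_sample_excluded_with_warning(self):
        samples = self._samples([30.0, 60.0])
        from nucleoclock.io_fragments import FragmentSet

        samples.append((FragmentSet("empty", {}), SampleMeta("empty", 50.0)))
        with pytest.warns(UserWarning, match="excluded"):
            fm = build_features(samples, "size_dist")
        assert fm.excluded == ["empty"]
        assert fm.n_samples == 2


class TestTrainClock:
    def test_perfectly_predictive_feature(self, rng):
        fm, ages = perfect_feature_cohort(rng)
        model, metrics = train_clock(fm, ages, k=3, seed=0)
        assert metrics.pearson_r == pytest.approx(1.0, abs=1e-9)
        assert metrics.median_abs_error < 1e-6

    def test_determinism(self, rng):
        fm, ages = perfect_feature_cohort(rng)
        m1, met1 = train_clock(fm, ages, k=3, seed=5)
        m2, met2 = train_clock(fm, ages, k=3, seed=5)
        np.testing.assert_array_equal(m1.coef, m2.coef)
        assert m1.train_ids == m2.train_ids
        assert met1.mse == met2.mse

    def test_no_leakage_from_test_rows(self, rng):
        """Replacing a test sample's features must not change the fit."""
        fm, ages = perfect_feature_cohort(rng, n=25)
        model, _ = train_clock(fm, ages, k=3, seed=1)
        test_pos = fm.sample_ids.index(model.test_ids[0])
        X2 = fm.X.copy()
        X2[test_pos] = rng.normal(size=X2.shape[1])
        fm2 = feature_matrix_from(X2)
        model2, _ = train_clock(fm2, ages, k=3, seed=1)
        np.testing.assert_array_equal(model.coef, model2.coef)
        np.testing.assert_array_equal(model.feature_means, model2.feature_means)
        np.testing.assert_array_equal(model.loadings, model2.loadings)

    def test_predictions_match_normal_equation_oracle(self, rng):
        fm, ages = perfect_feature_cohort(rng, n=20, n_features=6)
        model, _ = train_clock(fm, ages, k=2, seed=3)
        train_pos = [fm.sample_ids.index(s) for s in model.train_ids]
        Z = (fm.X[train_pos] - model.feature_means) / np.where(
            model.feature_sds > 0, model.feature_sds, 1.0
        )
        T = Z @ model.loadings.T
        A = np.column_stack([np.ones(len(T)), T])
        beta = np.linalg.lstsq(A, ages[train_pos], rcond=None)[0]
        pred_oracle = A @ beta
        pred = predict_age(model, fm.X[train_pos])
        np.testing.assert_allclose(pred, pred_oracle, atol=1e-8)

    def test_in_sample_residuals_have_zero_mean(self, rng):
        X = rng.normal(size=(30, 8))
        ages = rng.uniform(20, 90, 30)
        fm = feature_matrix_from(X)
        model, _ = train_clock(fm, ages, k=4, seed=0)
        train_pos = [fm.sample_ids.index(s) for s in model.train_ids]
        resid = predict_age(model, fm.X[train_pos]) - ages[train_pos]
        assert abs(resid.mean()) < 1e-8

    def test_all_zero_row_predicts_finite(self, rng):
        fm, ages = perfect_feature_cohort(rng)
        model, _ = train_clock(fm, ages, k=3, seed=0)
        pred = predict_age(model, np.zeros(fm.X.shape[1]))
        assert np.isfinite(pred).all()

    def test_k_too_large_rejected(self, rng):
        fm, ages = perfect_feature_cohort(rng, n=12)
        with pytest.raises(ValueError, match="n_train"):
            train_clock(fm, ages, k=11, seed=0)

    def test_grid_mismatch_rejected(self, rng):
        fm, ages = perfect_feature_cohort(rng)
        model, _ = train_clock(fm, ages, k=3, seed=0)
        with pytest.raises(ValueError, match="features"):
            predict_age(model, np.zeros(7))

    def test_split_is_stratified_by_age(self, rng):
        ages = np.concatenate([rng.uniform(20, 40, 12), rng.uniform(41, 60, 12), rng.uniform(61, 90, 12)])
        train_idx, test_idx = stratified_split(ages, 0.8, seed=2)
        assert len(train_idx) + len(test_idx) == 36
        # at least one test sample per tertile
        for lo, hi in ((20, 40), (41, 60), (61, 90)):
            assert np.any((ages[test_idx] >= lo) & (ages[test_idx] <= hi))

    def test_noise_features_do_not_wreck_the_benchmark_clock(self):
        """Appending i.i.d. noise columns to the synthetic-cohort feature
        matrix raises the test MedAE by at most noise-free MedAE + 2 years
        (seed-averaged).  The age signal of the real feature kinds lives in
        correlated high-variance directions, so the top training PCs stay
        anchored on it and uninformative isotropic columns are ignored."""
        mix = MixtureLink(
            w_mono0=0.45, w_di0=0.35, w_tri0=0.20, d_di=-0.003, d_tri=-0.0018
        )
        spec = CohortSpec(
            genome_length=300_000,
            n_fragments_per_subject=30_000,
            mixture=mix,
            seed=40,
        )
        deltas = []
        for seed in range(3):
            r = np.random.default_rng(1000 + seed)
            samples = []
            ages = r.uniform(25, 100, 40)
            for i, age in enumerate(ages):
                fs, _ = generate_subject(
                    spec, age, np.random.default_rng(seed * 100 + i), f"S{i}"
                )
                samples.append((fs, SampleMeta(f"S{i}", age)))
            fm = build_features(samples, "size_dist")
            _, met0 = train_clock(fm, ages, seed=seed)
            noisy = np.column_stack([fm.X, r.normal(size=(40, 100))])
            _, metn = train_clock(feature_matrix_from(noisy), ages, seed=seed)
            deltas.append(metn.median_abs_error - (met0.median_abs_error + 2.0))
        assert np.mean(deltas) <= 0.0

    def test_ridge_mode_also_learns(self, rng):
        fm, ages = perfect_feature_cohort(rng, n=40)
        model, metrics = train_clock(fm, ages, mode="ridge", seed=0)
        assert model.loadings is None
        assert metrics.pearson_r > 0.95


class TestMetrics:
    def test_perfect_predictions(self):
        ages = np.array([25.0, 50.0, 75.0])
        m = evaluate_metrics(ages, ages)
        assert m.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert m.mse == 0.0
        assert m.median_abs_error == 0.0

    def test_constant_offset(self):
        ages = np.array([25.0, 50.0, 75.0])
        m = evaluate_metrics(ages + 2, ages)
        assert m.pearson_r == pytest.approx(1.0)
        assert m.mse == pytest.approx(4.0)
        assert m.median_abs_error == pytest.approx(2.0)

    def test_matches_direct_formulas(self, rng):
        pred = rng.normal(50, 20, 200)
        chron = rng.normal(50, 20, 200)
        m = evaluate_metrics(pred, chron)
        r_oracle = np.sum((pred - pred.mean()) * (chron - chron.mean())) / np.sqrt(
            np.sum((pred - pred.mean()) ** 2) * np.sum((chron - chron.mean()) ** 2)
        )
        assert abs(m.pearson_r - r_oracle) < 1e-12
        assert abs(m.mse - np.mean((pred - chron) ** 2)) < 1e-12
        assert abs(m.median_abs_error - np.median(np.abs(pred - chron))) < 1e-12

    def test_zero_variance_predictions_flagged(self):
        m = evaluate_metrics(np.full(5, 50.0), np.arange(5, dtype=float))
        assert m.flagged and np.isnan(m.pearson_r)


class TestAUC:
    def test_scores_identical_to_labels(self):
        labels = np.array([0, 0, 1, 1, 0, 1])
        assert auc_mann_whitney(labels.astype(float), labels) == 1.0

    def test_rank_formula_matches_roc_integration_with_ties(self, rng):
        for _ in range(20):
            scores = rng.integers(0, 5, 50).astype(float)  # heavy ties
            labels = rng.integers(0, 2, 50).astype(bool)
            if labels.all() or not labels.any():
                continue
            ours = auc_mann_whitney(scores, labels)
            assert abs(ours - roc_auc_score(labels, scores)) < 1e-12

    def test_permuted_labels_centre_on_half(self, rng):
        scores = rng.normal(size=100)
        labels = np.zeros(100, dtype=bool)
        labels[:40] = True
        aucs = [
            auc_mann_whitney(scores, rng.permutation(labels)) for _ in range(200)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            auc_mann_whitney(np.arange(4.0), np.ones(4, dtype=bool))

    def test_classify_by_clock_scores(self):
        ages = np.array([30.0, 35.0, 40.0, 60.0, 70.0, 80.0])
        pred = ages + np.array([2.0, -1.0, 3.0, -2.0, 1.0, 0.0])
        assert classify_age_group(pred, ages, threshold_years=55.0) == 1.0

    def test_logistic_mode_on_separable_features(self, rng):
        ages = np.concatenate([rng.uniform(25, 35, 15), rng.uniform(75, 85, 15)])
        X = np.column_stack([ages + rng.normal(0, 1, 30), rng.normal(size=(30, 5))])
        fm = feature_matrix_from(X)
        auc = classify_age_group(fm, ages, threshold_years=55.0, mode="logistic", k=3)
        assert auc == 1.0
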