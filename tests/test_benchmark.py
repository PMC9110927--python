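"""Statistical learning benchmark: tests for every operation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aneumorph.benchmark import (
    BenchmarkError,
    DesignTransformer,
    FeatureMatrix,
    ModelConfig,
    assemble_design,
    compare_cut_configs,
    cross_validate,
    delta_prime,
    external_validate,
    feature_correlations,
    fit_lasso_lr,
    named_config,
    roc_metrics,
    univariate_tests,
)
from aneumorph.synthetic import CohortSpec, make_cohort

FAST_GRID = tuple(np.logspace(-2, 1, 6))


def generative_matrix(n=200, seed=0, beta_shape=1.5, beta_size=0.3,
                      location_effects=True, feature_noise=0.05):
    """Feature matrix whose columns are noisy readouts of the latents."""
    recs = [r for _, r in make_cohort(
        CohortSpec(n_cases=n, seed=seed, beta_shape=beta_shape,
                   beta_size=beta_size, location_effects=location_effects),
        generate_meshes=False,
    )]
    rng = np.random.default_rng(seed + 1)
    X = pd.DataFrame({
        "NSI": [r.params["z_irr"] for r in recs] + feature_noise * rng.standard_normal(n),
        "aSz": [r.params["z_size"] for r in recs] + feature_noise * rng.standard_normal(n),
        "noise": rng.standard_normal(n),
    })
    fm = FeatureMatrix(X=X, y=[r.ruptured for r in recs],
                       location=[r.location for r in recs])
    return fm, recs


class TestUnivariateTests:
    def test_identical_groups_not_significant(self):
        X = pd.DataFrame({"f": [1.0, 2, 3, 1, 2, 3]})
        fm = FeatureMatrix(X=X, y=[True, True, True, False, False, False])
        stats = univariate_tests(fm)
        assert stats.table.loc["f", "t"] == pytest.approx(0.0, abs=1e-12)
        assert not stats.table.loc["f", "significant"]

    def test_textbook_pooled_t(self):
        X = pd.DataFrame({"f": [1.0, 2, 3, 4, 5, 6]})
        fm = FeatureMatrix(X=X, y=[True, True, True, False, False, False])
        stats = univariate_tests(fm)
        assert stats.table.loc["f", "t"] == pytest.approx(-3.674, abs=1e-3)
        assert stats.table.loc["f", "p"] == pytest.approx(0.0214, abs=1e-3)

    def test_bonferroni_cutoff(self):
        X = pd.DataFrame({"f": [1.0, 2, 3, 4, 5, 6]})
        fm = FeatureMatrix(X=X, y=[True, True, True, False, False, False])
        stats = univariate_tests(fm, d=150)
        assert stats.d == 150
        assert stats.alpha / stats.d == pytest.approx(0.05 / 150)
        # p = 0.021 is significant at 0.05 but not at 0.05/150
        assert not stats.table.loc["f", "significant"]
        assert univariate_tests(fm, d=1).table.loc["f", "significant"]

    def test_tiny_class_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2, 3]})
        with pytest.raises(BenchmarkError):
            univariate_tests(FeatureMatrix(X=X, y=[True, False, False]))


class TestAssembleDesign:
    def test_standardization_on_training_rows(self):
        fm, _ = generative_matrix()
        design, t = assemble_design(fm, ModelConfig(name="all"))
        assert design.mean(axis=0) == pytest.approx(np.zeros(3), abs=1e-9)
        assert design.std(axis=0) == pytest.approx(np.ones(3), abs=1e-9)

    def test_perfectly_correlated_features_give_one_component(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(100)
        X = pd.DataFrame({"a": base, "b": 2 * base + 1, "c": -base})
        fm = FeatureMatrix(X=X, y=([True, False] * 50))
        _, t = assemble_design(fm, ModelConfig(name="pca", use_pca=True))
        assert t.n_components_ == 1

    def test_pca_component_count_matches_eigen_oracle(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((100, 20)),
                         columns=[f"f{i}" for i in range(20)])
        fm = FeatureMatrix(X=X, y=([True, False] * 50))
        _, t = assemble_design(fm, ModelConfig(name="pca", use_pca=True))
        z = (X.values - X.values.mean(0)) / X.values.std(0)
        evals = np.sort(np.linalg.eigvalsh(np.cov(z.T)))[::-1]
        k_oracle = int(np.searchsorted(np.cumsum(evals) / evals.sum(), 0.90) + 1)
        assert t.n_components_ == k_oracle

    def test_location_dummies_unstandardized_one_hot(self):
        fm, _ = generative_matrix(n=50)
        design, t = assemble_design(fm, ModelConfig(name="loc", features=(),
                                                    use_location=True))
        assert design.shape == (50, 12)
        assert set(np.unique(design)) == {0.0, 1.0}
        assert (design.sum(axis=1) == 1).all()

    def test_transformer_state_reusable_on_heldout_rows(self):
        fm, _ = generative_matrix()
        tr_rows = np.arange(0, 150)
        te_rows = np.arange(150, 200)
        _, t = assemble_design(fm.subset(tr_rows), ModelConfig(name="all"))
        held = t.transform(fm.subset(te_rows))
        # held-out standardization uses training stats: means differ from 0
        assert np.abs(held.mean(axis=0)).max() > 1e-4

    def test_zero_variance_feature_dropped(self, caplog):
        X = pd.DataFrame({"f": np.arange(10.0), "const": np.ones(10)})
        fm = FeatureMatrix(X=X, y=[True, False] * 5)
        import logging

        with caplog.at_level(logging.WARNING, logger="aneumorph.benchmark"):
            design, t = assemble_design(fm, ModelConfig(name="all"))
        assert design.shape[1] == 1
        assert t.columns_ == ["f"]


class TestLassoLR:
    def test_separable_feature_reaches_auc_one(self):
        design = np.linspace(-1, 1, 40).reshape(-1, 1)
        y = (design.ravel() > 0).astype(int)
        model, lam = fit_lasso_lr(design, y, lambda_grid=(0.01,), seed=0)
        scores = model.predict_proba(design)[:, 1]
        assert roc_metrics(scores, y.astype(bool)).auc == 1.0

    def test_huge_lambda_shrinks_all_coefficients(self):
        rng = np.random.default_rng(0)
        design = rng.standard_normal((100, 5))
        y = (rng.random(100) < 0.4).astype(int)
        model, _ = fit_lasso_lr(design, y, lambda_grid=(1e6,), seed=0)
        assert np.allclose(model.coef_, 0.0)

    def test_sign_recovery_on_generative_model(self):
        rng = np.random.default_rng(1)
        n = 500
        X = rng.standard_normal((n, 5))
        beta = np.array([2.0, -1.5, 1.0, 0.0, 0.0])
        p = 1 / (1 + np.exp(-(X @ beta)))
        y = (rng.random(n) < p).astype(int)
        model, _ = fit_lasso_lr(X, y, lambda_grid=FAST_GRID, seed=0)
        coef = model.coef_.ravel()
        assert np.sign(coef[0]) == 1 and np.sign(coef[1]) == -1 and np.sign(coef[2]) == 1
        assert abs(coef[0]) > abs(coef[3]) and abs(coef[0]) > abs(coef[4])

    def test_single_class_rejected(self):
        with pytest.raises(BenchmarkError):
            fit_lasso_lr(np.ones((10, 1)), np.ones(10), seed=0)


class TestRocMetrics:
    def test_worked_example(self):
        m = roc_metrics([0.1, 0.4, 0.35, 0.8], [False, False, True, True])
        assert m.auc == 0.75

    def test_perfect_separation(self):
        m = roc_metrics([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        assert m.auc == 1.0
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_negation_symmetry(self):
        rng = np.random.default_rng(0)
        s = rng.random(50)
        y = rng.random(50) < 0.4
        assert roc_metrics(-s, y).auc == pytest.approx(1 - roc_metrics(s, y).auc)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_auc_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        y = rng.random(n) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        s = np.round(rng.random(n), 1)  # coarse scores force ties
        pos, neg = s[y], s[~y]
        wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
        oracle = wins / (len(pos) * len(neg))
        assert roc_metrics(s, y).auc == pytest.approx(oracle, rel=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(BenchmarkError):
            roc_metrics([0.3, 0.6], [True, True])


class TestCrossValidate:
    def test_exactly_100_evaluations(self):
        fm, _ = generative_matrix(n=150)
        cfg = ModelConfig(name="NSI", features=("NSI",), lambda_grid=FAST_GRID)
        cv = cross_validate(fm, cfg, folds=5, repeats=20, seed=0)
        assert len(cv.evaluations) == 100
        assert cv.evaluations["repeat"].nunique() == 20

    def test_deterministic_under_fixed_seed(self):
        fm, _ = generative_matrix(n=120)
        cfg = ModelConfig(name="NSI", features=("NSI",), lambda_grid=FAST_GRID)
        a = cross_validate(fm, cfg, repeats=3, seed=5)
        b = cross_validate(fm, cfg, repeats=3, seed=5)
        assert a.evaluations.equals(b.evaluations)
        assert np.array_equal(a.final_model.estimator.coef_, b.final_model.estimator.coef_)

    def test_label_permutation_gives_chance_auc(self):
        fm, _ = generative_matrix(n=200, seed=4)
        rng = np.random.default_rng(0)
        perm = FeatureMatrix(X=fm.X, y=rng.permutation(fm.y), location=fm.location)
        cfg = ModelConfig(name="NSI", features=("NSI",), lambda_grid=FAST_GRID)
        cv = cross_validate(perm, cfg, repeats=5, seed=1)
        assert 0.44 <= cv.summary.loc["auc", "mean"] <= 0.56

    def test_no_leakage_from_test_fold_labels(self):
        # permuting test-fold labels must not change the fitted transformers
        # or the chosen lambda: both are functions of the training rows only
        fm, _ = generative_matrix(n=120, seed=2)
        tr = np.arange(0, 90)
        te = np.arange(90, 120)
        cfg = ModelConfig(name="NSI", features=("NSI", "aSz"), lambda_grid=FAST_GRID)
        design, t1 = assemble_design(fm.subset(tr), cfg)
        m1, lam1 = fit_lasso_lr(design, fm.subset(tr).y, cfg.lambda_grid, seed=0)
        y2 = fm.y.copy()
        y2[te] = np.random.default_rng(0).permutation(y2[te])
        fm2 = FeatureMatrix(X=fm.X, y=y2, location=fm.location)
        design2, t2 = assemble_design(fm2.subset(tr), cfg)
        m2, lam2 = fit_lasso_lr(design2, fm2.subset(tr).y, cfg.lambda_grid, seed=0)
        assert lam1 == lam2
        assert np.array_equal(m1.coef_, m2.coef_)
        assert np.array_equal(t1.mean_, t2.mean_)

    def test_too_few_samples_per_class_rejected(self):
        X = pd.DataFrame({"f": np.arange(8.0)})
        fm = FeatureMatrix(X=X, y=[True] * 3 + [False] * 5)
        with pytest.raises(BenchmarkError):
            cross_validate(fm, ModelConfig(name="f", features=("f",)), folds=5)

    def test_named_configs_resolve(self):
        for name in ("MAX", "MAX+LOC", "BUP", "BUP+LOC", "NSI+LOC", "Zsurf6+LOC", "LOC"):
            cfg = named_config(name)
            assert cfg.name == name
        with pytest.raises(BenchmarkError):
            named_config("nope")


class TestLocationModel:
    def test_location_only_model_matches_prior_oracle(self):
        # cohort whose rupture odds depend on location alone; the best any
        # location model can do is the AUC of the assigned priors
        from aneumorph.benchmark import _fast_auc
        from aneumorph.synthetic import location_priors

        spec = CohortSpec(n_cases=400, beta_shape=0.0, beta_size=0.0,
                          noise_scale=0.0, seed=12)
        recs = [r for _, r in make_cohort(spec, generate_meshes=False)]
        priors = location_priors()
        y = np.array([r.ruptured for r in recs])
        oracle = _fast_auc(y, np.array([priors[r.location] for r in recs]))
        rng = np.random.default_rng(0)
        fm = FeatureMatrix(
            X=pd.DataFrame({"noise": rng.standard_normal(len(recs))}),
            y=y, location=[r.location for r in recs],
        )
        cv = cross_validate(
            fm, ModelConfig(name="LOC", features=(), use_location=True,
                            lambda_grid=FAST_GRID),
            repeats=5, seed=0,
        )
        assert cv.summary.loc["auc", "mean"] == pytest.approx(oracle, abs=0.05)


class TestExternalValidate:
    def test_self_validation_close_to_training(self):
        fm, _ = generative_matrix(n=200, seed=6)
        cfg = ModelConfig(name="NSI", features=("NSI",), lambda_grid=FAST_GRID)
        cv = cross_validate(fm, cfg, repeats=3, seed=0)
        train_auc = roc_metrics(cv.final_model.decision_scores(fm), fm.y).auc
        ext = external_validate(cv.final_model, fm, resamples=100, seed=1)
        assert ext.loc["auc", "mean"] == pytest.approx(train_auc, abs=0.02)

    def test_flipped_association_gives_auc_below_half(self):
        fm, _ = generative_matrix(n=200, seed=7)
        cfg = ModelConfig(name="NSI", features=("NSI",), lambda_grid=FAST_GRID)
        cv = cross_validate(fm, cfg, repeats=3, seed=0)
        flipped = FeatureMatrix(X=-fm.X, y=fm.y, location=fm.location)
        ext = external_validate(cv.final_model, flipped, resamples=50, seed=1)
        assert ext.loc["auc", "mean"] < 0.5

    def test_distribution_shift_drops_auc(self):
        fm, recs = generative_matrix(n=300, seed=8)
        cfg = ModelConfig(name="two", features=("NSI", "aSz"), lambda_grid=FAST_GRID)
        cv = cross_validate(fm, cfg, repeats=3, seed=0)
        internal = cv.summary.loc["auc", "mean"]
        # shifted external cohort: weaker shape effect, larger unruptured sizes
        fm_ext, _ = generative_matrix(n=300, seed=99, beta_shape=0.4)
        shift = fm_ext.X.copy()
        shift.loc[~fm_ext.y, "aSz"] += 1.0
        fm_ext = FeatureMatrix(X=shift, y=fm_ext.y, location=fm_ext.location)
        ext = external_validate(cv.final_model, fm_ext, resamples=50, seed=1)
        assert ext.loc["auc", "mean"] < internal - 0.05


class TestDeltaPrime:
    def test_identical_cuts_give_zero(self):
        assert delta_prime(np.zeros(20)) == 0.0

    def test_hand_computed_example(self):
        assert delta_prime(np.array([1.0, 2, 3, 4, 5])) == pytest.approx(1.5)

    def test_constant_shift_flagged_infinite(self):
        assert delta_prime(np.full(10, 0.3)) == np.inf

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_direct_median_iqr(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.standard_normal(21)
        q1, q3 = np.percentile(d, [25, 75])
        assert delta_prime(d) == pytest.approx(np.median(d) / (q3 - q1))

    def test_category_means(self):
        idx = [f"c{i}" for i in range(10)]
        a = pd.DataFrame({"NSI": np.arange(10.0), "GLN": np.arange(10.0) * 2},
                         index=idx)
        b = pd.DataFrame({"NSI": np.zeros(10), "GLN": np.arange(10.0)}, index=idx)
        dp, means = compare_cut_configs(a, b)
        assert dp["NSI"] == pytest.approx(delta_prime(np.arange(10.0)))
        assert means["GI shape"] == pytest.approx(dp["NSI"])
        assert means["curvature"] == pytest.approx(dp["GLN"])


class TestCutComparisonIntegration:
    def test_delta_prime_on_dome_vs_ninja_cohort(self):
        # the same cases measured under planar and non-planar neck cuts
        from aneumorph.features import feature_frame, compute_descriptor

        frames = {}
        for cut in ("dome", "ninja"):
            cohort = make_cohort(
                CohortSpec(n_cases=15, seed=21, resolution=12, cut_type=cut)
            )
            for mesh, rec in cohort:
                rec.descriptor = compute_descriptor(
                    mesh, cut_type=cut, families=("geometry",)
                )
            frames[cut] = feature_frame([r for _, r in cohort])
        dp, means = compare_cut_configs(frames["dome"], frames["ninja"])
        assert np.isfinite(dp["NSI"])
        assert "GI shape" in means.index and "GI size" in means.index
        # differing cuts produce nonzero differences somewhere
        assert dp.abs().max() > 0

class TestCorrelations:
    def test_self_correlation_is_one(self):
        fm, _ = generative_matrix(n=50)
        c = feature_correlations(fm)
        assert np.allclose(np.diag(c.values), 1.0)

    def test_linear_relation(self):
        X = pd.DataFrame({"x": np.arange(10.0), "y": 2 * np.arange(10.0) + 1})
        fm = FeatureMatrix(X=X, y=[True, False] * 5)
        assert feature_correlations(fm, "pearson").loc["x", "y"] == pytest.approx(1.0)
        assert feature_correlations(fm, "spearman").loc["x", "y"] == pytest.approx(1.0)

    def test_cubic_relation_spearman_perfect_pearson_not(self):
        x = np.array([-2.0, -1, 0, 1, 2])
        X = pd.DataFrame({"x": x, "y": x**3})
        fm = FeatureMatrix(X=X, y=[True, False, True, False, True])
        assert feature_correlations(fm, "spearman").loc["x", "y"] == pytest.approx(1.0)
        # direct Pearson formula oracle
        r = np.corrcoef(x, x**3)[0, 1]
        assert feature_correlations(fm, "pearson").loc["x", "y"] == pytest.approx(r)
        assert r < 1.0

    def test_too_few_rows_rejected(self):
        X = pd.DataFrame({"x": [1.0, 2]})
        with pytest.raises(BenchmarkError):
            feature_correlations(FeatureMatrix(X=X, y=[True, False]))
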