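"""Pooled-diagonal LDA, quantile mapping, and the MCMC tree forest."""

import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import norm

from osascreen.classifiers import (ForestEnsemble, QuantileMap, SamplerConfig,
                                   TreeSpec, ensemble_from_json,
                                   ensemble_to_json, fit_lda,
                                   fit_quantile_map, predict_forest,
                                   predict_lda, run_sampler,
                                   tree_contribution)
from osascreen.evaluation import rank_auc


def two_gaussians(n_per_class, delta, seed=0, p=1):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0.0, 1.0, (n_per_class, p)),
                   rng.normal(delta, 1.0, (n_per_class, p))])
    y = np.r_[np.zeros(n_per_class), np.ones(n_per_class)].astype(int)
    return X, y


class TestLDA:
    def test_boundary_at_analytic_midpoint(self):
        """Equal priors/variances in 1-D: the posterior crosses 0.5 at the
        midpoint of the class means (here 2.0)."""
        X, y = two_gaussians(2000, 4.0, seed=1)
        model = fit_lda(X, y)
        # equal priors & pooled variance -> boundary = mean of class means
        boundary = model.class_means.mean()
        assert abs(boundary - 2.0) < 0.1
        s, _ = predict_lda(model, np.array([[boundary]]))
        assert s[0] == pytest.approx(0.5, abs=1e-9)

    def test_error_rate_approaches_bayes_rate(self):
        """With unit variances and means 0/2 the Bayes error is Phi(-1)."""
        X, y = two_gaussians(5000, 2.0, seed=2)
        model = fit_lda(X, y)
        Xt, yt = two_gaussians(5000, 2.0, seed=3)
        _, pred = predict_lda(model, Xt)
        err = np.mean(pred != yt)
        assert abs(err - norm.cdf(-1.0)) < 0.02

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_lda(np.random.default_rng(0).normal(size=(10, 2)), np.ones(10))

    def test_zero_variance_feature_named(self):
        X, y = two_gaussians(20, 1.0, seed=4, p=2)
        X[:, 1] = 3.0
        with pytest.raises(ValueError, match="1"):
            fit_lda(X, y)

    def test_duplicated_columns_get_identical_parameters(self):
        X, y = two_gaussians(50, 1.0, seed=5)
        X2 = np.hstack([X, X])
        m = fit_lda(X2, y)
        assert m.class_means[:, 0] == pytest.approx(m.class_means[:, 1])
        assert m.pooled_diag_variance[0] == pytest.approx(
            m.pooled_diag_variance[1])

    def test_posteriors_normalized_and_symmetric(self):
        X, y = two_gaussians(200, 2.0, seed=6)
        model = fit_lda(X, y)
        s, lab = predict_lda(model, model.class_means)
        assert s[0] < 0.5 < s[1]
        # complementary scores sum to one by construction
        assert np.all((s >= 0) & (s <= 1))


class TestQuantileMap:
    def test_training_median_maps_to_zero(self):
        rng = np.random.default_rng(7)
        X = rng.lognormal(size=(101, 1))
        qm = fit_quantile_map(X)
        assert np.median(qm.transform(X)) == pytest.approx(0.0, abs=1e-12)

    def test_three_distinct_values(self):
        qm = fit_quantile_map(np.array([[1.0], [2.0], [3.0]]))
        z = qm.transform(np.array([[1.0], [2.0], [3.0]]))[:, 0]
        assert z == pytest.approx(norm.ppf([0.25, 0.5, 0.75]))

    def test_order_preserved_and_extremes_clamped(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 1))
        qm = fit_quantile_map(X)
        grid = np.linspace(X.min() - 5, X.max() + 5, 101)[:, None]
        z = qm.transform(grid)[:, 0]
        assert np.all(np.diff(z) >= 0)
        assert z[0] == qm.knots_z[0][0] and z[-1] == qm.knots_z[0][-1]

    def test_missing_values_stay_missing(self):
        X = np.array([[1.0], [2.0], [np.nan], [4.0]])
        qm = fit_quantile_map(X)
        assert np.isnan(qm.transform(X)[2, 0])

    def test_all_missing_feature_rejected(self):
        with pytest.raises(ValueError):
            fit_quantile_map(np.full((5, 1), np.nan))


class TestTreeContribution:
    def _tree(self, **kw):
        base = dict(split_feature_1=0, split_feature_2=1, split_value_1=1.0,
                    split_value_2=1.0, contrib_feature=2, slope=2.0,
                    offset=1.0, missing_contrib=0.7)
        base.update(kw)
        return TreeSpec(**base)

    def test_passes_both_splits(self):
        assert tree_contribution(self._tree(), [0.0, 0.5, 0.5]) == 2.0

    def test_fails_first_split(self):
        assert tree_contribution(self._tree(), [1.5, 0.5, 0.5]) == 0.0

    def test_missing_contrib_feature_uses_surrogate(self):
        assert tree_contribution(self._tree(), [0.0, 0.0, np.nan]) == 0.7

    def test_missing_split_feature_fails_split(self):
        assert tree_contribution(self._tree(), [np.nan, 0.0, 0.5]) == 0.0


class TestForest:
    def test_null_forest_predicts_mean_outcome(self):
        """Zero contributions: p = inverse-logit(logit(mean outcome)) exactly."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 3))
        qm = fit_quantile_map(X)
        for mean_y in (0.5, 0.25):
            ens = ForestEnsemble(
                feats=np.zeros((1, 5, 3), dtype=int),
                splits=np.zeros((1, 5, 2)), slopes=np.zeros((1, 5)),
                offsets=np.zeros((1, 5)), intercept=float(logit(mean_y)),
                quantile_map=qm, config=SamplerConfig())
            p = predict_forest(ens, rng.normal(size=(7, 3)))
            assert np.allclose(p, mean_y)

    def test_sampler_learns_separable_data(self):
        X, y = two_gaussians(100, 3.0, seed=10, p=2)
        ens = run_sampler(X, y, SamplerConfig(n_trees=50, n_iterations=10_000,
                                              n_restarts=2, seed=11))
        p = predict_forest(ens, X)
        assert rank_auc(p, y) >= 0.95
        assert np.all((p > 0) & (p < 1))

    def test_bit_identical_under_fixed_seed(self):
        X, y = two_gaussians(50, 2.0, seed=12, p=2)
        cfg = SamplerConfig(n_trees=20, n_iterations=2000, thin_interval=100,
                            n_restarts=2, seed=13)
        e1 = run_sampler(X, y, cfg)
        e2 = run_sampler(X, y, cfg)
        for a, b in ((e1.feats, e2.feats), (e1.splits, e2.splits),
                     (e1.slopes, e2.slopes), (e1.offsets, e2.offsets)):
            assert np.array_equal(a, b)

    def test_greedy_chain_loglik_non_decreasing(self):
        X, y = two_gaussians(50, 2.0, seed=14, p=2)
        ens = run_sampler(X, y, SamplerConfig(n_trees=20, n_iterations=2000,
                                              thin_interval=100, n_restarts=1,
                                              seed=15), greedy=True)
        tr = ens.loglik_traces[0]
        assert np.all(np.diff(tr) >= 0)

    def test_stochastic_chain_beats_null_on_separable_data(self):
        X, y = two_gaussians(60, 3.0, seed=16, p=2)
        ens = run_sampler(X, y, SamplerConfig(n_trees=20, n_iterations=4000,
                                              thin_interval=200, n_restarts=1,
                                              seed=17))
        null_ll = len(y) * (0.5 * np.log(0.5) + 0.5 * np.log(0.5))
        assert ens.loglik_traces[0][-1] > null_ll

    def test_calibrated_on_label_independent_features(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(120, 3))
        y = (rng.random(120) < 0.3).astype(int)
        ens = run_sampler(X, y, SamplerConfig(n_trees=20, n_iterations=4000,
                                              thin_interval=200, n_restarts=1,
                                              seed=19))
        p = predict_forest(ens, X)
        assert abs(p.mean() - y.mean()) < 0.05

    def test_handles_missing_features(self):
        X, y = two_gaussians(60, 3.0, seed=20, p=3)
        X[::7, 1] = np.nan
        ens = run_sampler(X, y, SamplerConfig(n_trees=20, n_iterations=2000,
                                              thin_interval=200, n_restarts=1,
                                              seed=21))
        p = predict_forest(ens, X)
        assert np.isfinite(p).all()
        assert rank_auc(p, y) > 0.8

    def test_degenerate_labels_rejected(self):
        X = np.random.default_rng(22).normal(size=(20, 2))
        with pytest.raises(ValueError):
            run_sampler(X, np.ones(20), SamplerConfig())

    def test_json_round_trip(self):
        X, y = two_gaussians(30, 2.0, seed=23, p=2)
        cfg = SamplerConfig(n_trees=5, n_iterations=500, thin_interval=50,
                            n_restarts=1, seed=24)
        ens = run_sampler(X, y, cfg)
        back = ensemble_from_json(ensemble_to_json(ens))
        assert np.allclose(predict_forest(back, X), predict_forest(ens, X))
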