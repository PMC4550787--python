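"""The two severity classifiers.

LDA here is the pooled diagonal-covariance Gaussian discriminant
(essentially naive Bayes with a shared per-feature variance): each class
gets a multivariate normal density with a diagonal covariance matrix pooled
across classes, and the posterior fixes the decision boundary.

The forest is an MCMC-sampled Bayesian tree ensemble.  Each tree selects a
subset of observations via two regression splits (mapped value <= split
value on two features) and gives that subset a linear contribution
slope * x[contrib_feature] + offset; a scaled surrogate stands in when the
contribution feature is missing.  A forest's prediction is
inverse-logit(intercept + sum of tree contributions) with the intercept
fixed at logit(mean training outcome).  A Metropolis–Hastings chain
re-randomizes two trees per iteration, accepts on the Bernoulli
log-likelihood, and after 20% burn-in stores forest snapshots at a fixed
interval; restarts are pooled and the ensemble prediction is the mean over
stored forests.  Training features are first mapped onto the quantiles of
a standard normal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit, logit

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# LDA (pooled diagonal covariance)
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    class_means: np.ndarray       # (2, p)
    pooled_diag_variance: np.ndarray  # (p,)
    class_priors: np.ndarray      # (2,), sums to 1


def fit_lda(X, y) -> LDAModel:
    """Fit per-class means and a single pooled per-feature variance.

    y must contain both classes; raises naming any feature whose pooled
    variance is zero (such a feature makes the density degenerate).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim == 1:
        X = X[:, None]
    classes = np.unique(y)
    if classes.shape[0] != 2:
        raise ValueError("both classes must be present")
    if not np.all(np.isfinite(X)):
        raise ValueError("LDA features must be finite (impute missing first)")
    means = np.vstack([X[y == c].mean(axis=0) for c in (0, 1)])
    n = X.shape[0]
    ss = sum(((X[y == c] - means[c]) ** 2).sum(axis=0) for c in (0, 1))
    var = ss / (n - 2)
    if np.any(var <= 0):
        bad = np.flatnonzero(var <= 0)
        raise ValueError(f"zero pooled variance in feature(s) {bad.tolist()}")
    priors = np.array([(y == 0).mean(), (y == 1).mean()])
    return LDAModel(class_means=means, pooled_diag_variance=var,
                    class_priors=priors)


def predict_lda(model: LDAModel, X):
    """Posterior probability of the positive class and argmax labels."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    if X.shape[1] != model.class_means.shape[1]:
        raise ValueError("feature count mismatch")
    v = model.pooled_diag_variance
    ll = np.empty((X.shape[0], 2))
    for c in (0, 1):
        z = (X - model.class_means[c]) ** 2 / v
        ll[:, c] = -0.5 * (z.sum(axis=1) + np.log(v).sum()) \
            + np.log(model.class_priors[c])
    ll -= ll.max(axis=1, keepdims=True)
    post = np.exp(ll)
    post /= post.sum(axis=1, keepdims=True)
    scores = post[:, 1]
    return scores, (scores >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# Normal quantile mapping
# ---------------------------------------------------------------------------

@dataclass
class QuantileMap:
    """Per-feature monotone map of training values onto normal quantiles.

    Training values get Phi^-1(rank / (n+1)) (average ranks for ties); new
    values are mapped by monotone interpolation between training knots and
    clamped at the trained extremes.  Missing values (NaN) stay missing.
    """

    knots_x: list   # per feature: increasing unique training values
    knots_z: list   # per feature: mapped values at those knots
    col_means: np.ndarray  # per-feature mean of mapped training values

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        one_d = X.ndim == 1
        if one_d:
            X = X[:, None]
        if X.shape[1] != len(self.knots_x):
            raise ValueError("feature count mismatch")
        out = np.full_like(X, np.nan, dtype=float)
        for j in range(X.shape[1]):
            ok = np.isfinite(X[:, j])
            out[ok, j] = np.interp(X[ok, j], self.knots_x[j], self.knots_z[j])
        return out[:, 0] if one_d else out


def fit_quantile_map(X) -> QuantileMap:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    kx, kz, means = [], [], []
    for j in range(X.shape[1]):
        v = X[np.isfinite(X[:, j]), j]
        if v.shape[0] < 3:
            raise ValueError(f"feature {j} has fewer than 3 non-missing values")
        ranks = stats.rankdata(v, method="average")
        z = stats.norm.ppf(ranks / (v.shape[0] + 1))
        order = np.argsort(v, kind="stable")
        vx, vz = v[order], z[order]
        uniq, idx = np.unique(vx, return_index=True)
        kx.append(uniq)
        kz.append(vz[idx])  # ties share a rank, hence share a mapped value
        means.append(z.mean())
    return QuantileMap(knots_x=kx, knots_z=kz, col_means=np.asarray(means))


# ---------------------------------------------------------------------------
# MCMC tree forest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeSpec:
    """One two-split tree with a linear leaf contribution.

    Indices refer to quantile-mapped feature space; an observation passes a
    split when its mapped value is <= the split value (a missing value at a
    split feature fails the split).
    """

    split_feature_1: int
    split_feature_2: int
    split_value_1: float
    split_value_2: float
    contrib_feature: int
    slope: float
    offset: float
    missing_contrib: float


def tree_contribution(tree: TreeSpec, observation) -> float:
    """Contribution of one tree to one quantile-mapped observation."""
    x = np.asarray(observation, dtype=float)
    for f, v in ((tree.split_feature_1, tree.split_value_1),
                 (tree.split_feature_2, tree.split_value_2)):
        xv = x[f]
        if not (np.isfinite(xv) and xv <= v):
            return 0.0
    xc = x[tree.contrib_feature]
    if not np.isfinite(xc):
        return float(tree.missing_contrib)
    return float(tree.slope * xc + tree.offset)


@dataclass
class Forest:
    """Array-backed forest: row k of each array is tree k."""

    feats: np.ndarray      # (n_trees, 3) int: split1, split2, contrib
    splits: np.ndarray     # (n_trees, 2)
    slopes: np.ndarray     # (n_trees,)
    offsets: np.ndarray    # (n_trees,)
    intercept: float

    @property
    def n_trees(self) -> int:
        return self.feats.shape[0]

    def tree(self, k: int, col_means) -> TreeSpec:
        return TreeSpec(int(self.feats[k, 0]), int(self.feats[k, 1]),
                        float(self.splits[k, 0]), float(self.splits[k, 1]),
                        int(self.feats[k, 2]), float(self.slopes[k]),
                        float(self.offsets[k]),
                        float(0.5 * self.slopes[k] * col_means[self.feats[k, 2]]))


@dataclass(frozen=True)
class SamplerConfig:
    n_trees: int = 50
    n_iterations: int = 10_000
    burn_in_fraction: float = 0.20
    thin_interval: int | None = None  # default: ~100 snapshots per restart
    n_restarts: int = 2
    seed: int = 0
    split_value_range: tuple = (-2.0, 2.0)

    def __post_init__(self):
        if not (0.0 < self.burn_in_fraction < 1.0):
            raise ValueError("burn_in_fraction must be in (0, 1)")
        if self.thin_interval is not None and self.thin_interval < 1:
            raise ValueError("thin_interval must be >= 1")

    def resolved_thin(self) -> int:
        if self.thin_interval is not None:
            return self.thin_interval
        return max(1, int(self.n_iterations * (1 - self.burn_in_fraction) / 100))


@dataclass
class ForestEnsemble:
    """Pooled stored forests from all restarts plus the quantile map."""

    feats: np.ndarray     # (n_forests, n_trees, 3) int
    splits: np.ndarray    # (n_forests, n_trees, 2)
    slopes: np.ndarray    # (n_forests, n_trees)
    offsets: np.ndarray   # (n_forests, n_trees)
    intercept: float
    quantile_map: QuantileMap
    config: SamplerConfig
    loglik_traces: list = field(default_factory=list)  # accepted ll per restart

    @property
    def n_forests(self) -> int:
        return self.feats.shape[0]


def _tree_contrib_vec(Xm, nan_mask, col_means, f, v, slope, offset):
    """Contribution vector of one tree over all observations (mapped space)."""
    with np.errstate(invalid="ignore"):
        mask = (Xm[:, f[0]] <= v[0]) & (Xm[:, f[1]] <= v[1])
    x3 = Xm[:, f[2]]
    contrib = slope * x3 + offset
    miss = 0.5 * slope * col_means[f[2]]
    contrib = np.where(nan_mask[:, f[2]], miss, contrib)
    return np.where(mask, contrib, 0.0)


def _bernoulli_loglik(z, y):
    # sum over observations of y*z - log(1 + e^z)
    return float(np.sum(y * z) - np.sum(np.logaddexp(0.0, z)))


def run_sampler(X, y, config: SamplerConfig,
                quantile_map: QuantileMap | None = None,
                greedy: bool = False) -> ForestEnsemble:
    """Fit the forest ensemble by Metropolis–Hastings sampling.

    Proposals re-randomize two trees jointly (features, split values
    uniform on the configured mapped-space range, slope/offset standard
    normal) and are accepted with probability min(1, exp(ll' - ll)) on the
    Bernoulli log-likelihood (symmetric proposal, flat prior).  With
    ``greedy`` the chain only accepts non-decreasing likelihood (used for
    diagnostics).  Restarts reinitialize the null forest under fresh seeds;
    all stored forests are pooled.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.unique(y).shape[0] != 2:
        raise ValueError("both classes must be present")
    thin = config.resolved_thin()
    if config.n_iterations < 10 * thin:
        raise ValueError("n_iterations must be >= 10 * thin_interval")
    qmap = quantile_map or fit_quantile_map(X)
    Xm = qmap.transform(X)
    nan_mask = ~np.isfinite(Xm)
    col_means = qmap.col_means
    n, p = Xm.shape
    intercept = float(logit(y.mean()))
    burn = int(config.burn_in_fraction * config.n_iterations)
    vlo, vhi = config.split_value_range

    all_feats, all_splits, all_slopes, all_offsets = [], [], [], []
    traces = []
    for restart in range(config.n_restarts):
        rng = np.random.default_rng([int(config.seed), restart])
        # Null initialization: random structure, zero slope/offset => zero
        # contribution from every tree (missing surrogate is zero too).
        feats = rng.integers(0, p, size=(config.n_trees, 3))
        splits = rng.uniform(vlo, vhi, size=(config.n_trees, 2))
        slopes = np.zeros(config.n_trees)
        offsets = np.zeros(config.n_trees)
        C = np.zeros((config.n_trees, n))
        S = np.zeros(n)
        ll = _bernoulli_loglik(intercept + S, y)
        trace = [ll]
        n_rejected_nonfinite = 0
        for it in range(config.n_iterations):
            i1 = int(rng.integers(config.n_trees))
            i2 = int(rng.integers(config.n_trees))
            while i2 == i1:
                i2 = int(rng.integers(config.n_trees))
            prop = []
            S_new = S - C[i1] - C[i2]
            for _ in (0, 1):
                f = rng.integers(0, p, size=3)
                v = rng.uniform(vlo, vhi, size=2)
                sl, of = rng.standard_normal(2)
                c = _tree_contrib_vec(Xm, nan_mask, col_means, f, v, sl, of)
                prop.append((f, v, sl, of, c))
                S_new = S_new + c
            ll_new = _bernoulli_loglik(intercept + S_new, y)
            if not np.isfinite(ll_new):
                n_rejected_nonfinite += 1
                accept = False
            elif greedy:
                accept = ll_new >= ll
            else:
                accept = np.log(rng.random()) < ll_new - ll
            if accept:
                for idx, (f, v, sl, of, c) in zip((i1, i2), prop):
                    feats[idx] = f
                    splits[idx] = v
                    slopes[idx] = sl
                    offsets[idx] = of
                    C[idx] = c
                S = S_new
                ll = ll_new
                trace.append(ll)
            if it >= burn and (it - burn) % thin == 0:
                all_feats.append(feats.copy())
                all_splits.append(splits.copy())
                all_slopes.append(slopes.copy())
                all_offsets.append(offsets.copy())
        if n_rejected_nonfinite:
            logger.warning("restart %d: rejected %d non-finite proposals",
                           restart, n_rejected_nonfinite)
        traces.append(np.asarray(trace))

    return ForestEnsemble(feats=np.asarray(all_feats),
                          splits=np.asarray(all_splits),
                          slopes=np.asarray(all_slopes),
                          offsets=np.asarray(all_offsets),
                          intercept=intercept, quantile_map=qmap,
                          config=config, loglik_traces=traces)


def predict_forest(ensemble: ForestEnsemble, X, mapped: bool = False) -> np.ndarray:
    """Mean over stored forests of inverse-logit(intercept + tree sums)."""
    if ensemble.n_forests == 0:
        raise ValueError("empty ensemble")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Xm = X if mapped else ensemble.quantile_map.transform(X)
    nan_mask = ~np.isfinite(Xm)
    col_means = ensemble.quantile_map.col_means
    nf, nt = ensemble.feats.shape[0], ensemble.feats.shape[1]
    f1 = ensemble.feats[:, :, 0].ravel()
    f2 = ensemble.feats[:, :, 1].ravel()
    f3 = ensemble.feats[:, :, 2].ravel()
    v1 = ensemble.splits[:, :, 0].ravel()
    v2 = ensemble.splits[:, :, 1].ravel()
    sl = ensemble.slopes.ravel()
    of = ensemble.offsets.ravel()
    with np.errstate(invalid="ignore"):
        mask = (Xm[:, f1] <= v1) & (Xm[:, f2] <= v2)
    x3 = Xm[:, f3]
    contrib = sl * x3 + of
    miss = 0.5 * sl * col_means[f3]
    contrib = np.where(np.isnan(x3), miss, contrib)
    contrib = np.where(mask, contrib, 0.0)          # (n, nf*nt)
    totals = contrib.reshape(X.shape[0], nf, nt).sum(axis=2) + ensemble.intercept
    return expit(totals).mean(axis=1)


def forest_log_likelihood(ensemble: ForestEnsemble, X, y) -> float:
    """Bernoulli log-likelihood of labels under the ensemble-mean probability."""
    p = predict_forest(ensemble, X)
    y = np.asarray(y, dtype=float)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def ensemble_to_json(ensemble: ForestEnsemble) -> str:
    cfg = ensemble.config
    return json.dumps(dict(
        feats=ensemble.feats.tolist(), splits=ensemble.splits.tolist(),
        slopes=ensemble.slopes.tolist(), offsets=ensemble.offsets.tolist(),
        intercept=ensemble.intercept,
        quantile_map=dict(knots_x=[k.tolist() for k in ensemble.quantile_map.knots_x],
                          knots_z=[k.tolist() for k in ensemble.quantile_map.knots_z],
                          col_means=ensemble.quantile_map.col_means.tolist()),
        config=dict(n_trees=cfg.n_trees, n_iterations=cfg.n_iterations,
                    burn_in_fraction=cfg.burn_in_fraction,
                    thin_interval=cfg.thin_interval, n_restarts=cfg.n_restarts,
                    seed=cfg.seed, split_value_range=list(cfg.split_value_range))))


def ensemble_from_json(text: str) -> ForestEnsemble:
    d = json.loads(text)
    qm = QuantileMap(knots_x=[np.asarray(k) for k in d["quantile_map"]["knots_x"]],
                     knots_z=[np.asarray(k) for k in d["quantile_map"]["knots_z"]],
                     col_means=np.asarray(d["quantile_map"]["col_means"]))
    c = d["config"]
    cfg = SamplerConfig(n_trees=c["n_trees"], n_iterations=c["n_iterations"],
                        burn_in_fraction=c["burn_in_fraction"],
                        thin_interval=c["thin_interval"],
                        n_restarts=c["n_restarts"], seed=c["seed"],
                        split_value_range=tuple(c["split_value_range"]))
    return ForestEnsemble(feats=np.asarray(d["feats"], dtype=int),
                          splits=np.asarray(d["splits"]),
                          slopes=np.asarray(d["slopes"]),
                          offsets=np.asarray(d["offsets"]),
                          intercept=float(d["intercept"]),
                          quantile_map=qm, config=cfg)
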