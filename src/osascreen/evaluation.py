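"""Orchestration: cross-validation, grid search, metrics, and both pipelines.

Severity arm: outer 5-fold subject-stratified CV; within each outer
training set, five random 70:30 subject splits drive a grid search over
every (dsr, m, r) combination scored by validation accuracy, the modal
winner is refit on the full training set, and the held-out fold is scored
for two feature sets (MSE alone, MSE + demographics) with LDA and with the
MCMC forest.

Event arm: for each event window size and feature-block combination,
subject-stratified 5-fold LDA cross-validation of F vs S/N.

Folds are stratified by *subject*, never by event: events of one subject
always land in one fold, so no subject leaks across the train/test split.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import mse
from .classifiers import (SamplerConfig, fit_lda, predict_lda, run_sampler,
                          predict_forest)
from .preprocess import (DSR_GRID, EVENT_WINDOWS, clip_events,
                         extract_analysis_window, log_variance_envelope)
from .event_features import build_event_features
from .synthetic import CohortBundle, Demographics

logger = logging.getLogger(__name__)

METRIC_NAMES = ("se", "sp", "ppv", "npv", "ac", "auc")


# ---------------------------------------------------------------------------
# Folds and metrics
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    k: int
    assignments: dict  # subject_id -> fold index
    seed: int

    def fold_subjects(self, fold: int):
        return [s for s, f in self.assignments.items() if f == fold]

    def train_subjects(self, fold: int):
        return [s for s, f in self.assignments.items() if f != fold]


def stratified_subject_folds(subject_ids, labels, k: int, seed: int) -> FoldPlan:
    """Partition subjects into k folds, balancing the class mix per fold.

    Within each class, subjects are shuffled and dealt round-robin; the
    dealing position carries over between classes so fold sizes stay within
    one subject of each other.
    """
    subject_ids = list(subject_ids)
    labels = np.asarray(labels, dtype=int)
    if k > len(subject_ids):
        raise ValueError(f"k={k} exceeds {len(subject_ids)} subjects")
    if np.unique(labels).shape[0] < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    assignments = {}
    pos = 0
    for cls in (1, 0):
        members = [s for s, l in zip(subject_ids, labels) if l == cls]
        order = rng.permutation(len(members))
        for i in order:
            assignments[members[i]] = pos % k
            pos += 1
    return FoldPlan(k=k, assignments=assignments, seed=seed)


@dataclass
class Metrics:
    se: float
    sp: float
    ppv: float
    npv: float
    ac: float
    auc: float

    def as_dict(self):
        return {m: getattr(self, m) for m in METRIC_NAMES}


def rank_auc(scores, labels) -> float:
    """AUC via the Mann-Whitney rank statistic; tied scores count half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    from scipy.stats import rankdata
    ranks = rankdata(scores, method="average")
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(scores, labels, threshold: float = 0.5) -> Metrics:
    """Confusion-matrix metrics (percent) at a threshold, plus rank AUC.

    Predicted positive iff score >= threshold.  PPV/NPV are NaN when their
    denominator is zero (e.g. the classifier never predicts positive).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape[0] == 0:
        raise ValueError("empty input")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))

    def pct(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    return Metrics(se=pct(tp, tp + fn), sp=pct(tn, tn + fp),
                   ppv=pct(tp, tp + fp), npv=pct(tn, tn + fn),
                   ac=pct(tp + tn, tp + fn + tn + fp),
                   auc=rank_auc(scores, labels))


def threshold_classifier(values, threshold: float) -> np.ndarray:
    """Predict positive iff value >= threshold (clinical single-feature rule)."""
    return (np.asarray(values, dtype=float) >= threshold).astype(int)


def clinical_baseline(metadata: pd.DataFrame,
                      thresholds: dict | None = None) -> pd.DataFrame:
    """Single-feature clinical-threshold baselines against the cohort label.

    Default rows: gender (male = positive), age 50, neck 40 cm, BMI 35,
    ESS 15, and AHI at 5/10/15/20/30 events/h.
    """
    if thresholds is None:
        thresholds = {"age": [50.0], "neck": [40.0], "bmi": [35.0],
                      "ess": [15.0], "true_ahi": [5.0, 10.0, 15.0, 20.0, 30.0]}
    y = metadata["label"].to_numpy(int)
    rows = []
    male = (metadata["gender"] == "m").astype(float).to_numpy()
    m = compute_metrics(male, y, threshold=0.5)
    rows.append(dict(feature="gender", threshold="male", **m.as_dict()))
    for feat, ths in thresholds.items():
        vals = metadata[feat].to_numpy(float)
        for th in ths:
            m = compute_metrics(vals, y, threshold=th)
            rows.append(dict(feature=feat, threshold=th, **m.as_dict()))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Classifier adapters over severity feature tables
# ---------------------------------------------------------------------------

class _LdaAdapter:
    """LDA on possibly-missing features: train-mean imputation, drop
    degenerate (all-missing or zero-variance) columns."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.col_means = np.nanmean(np.where(np.isfinite(X), X, np.nan), axis=0)
        self.col_means = np.where(np.isfinite(self.col_means), self.col_means, 0.0)
        Xi = self._impute(X)
        var = Xi.var(axis=0)
        self.keep = var > 1e-12
        if not self.keep.any():
            raise ValueError("no usable features")
        self.model = fit_lda(Xi[:, self.keep], y)
        return self

    def _impute(self, X):
        X = np.asarray(X, dtype=float)
        bad = ~np.isfinite(X)
        return np.where(bad, np.broadcast_to(self.col_means, X.shape), X)

    def predict_scores(self, X):
        scores, _ = predict_lda(self.model, self._impute(X)[:, self.keep])
        return scores


class _ForestAdapter:
    """MCMC forest on possibly-missing features (handled natively);
    all-missing columns are dropped before quantile mapping."""

    def __init__(self, sampler_config: SamplerConfig):
        self.cfg = sampler_config

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        counts = np.isfinite(X).sum(axis=0)
        self.keep = counts >= 3
        if not self.keep.any():
            raise ValueError("no usable features")
        self.ensemble = run_sampler(X[:, self.keep], y, self.cfg)
        return self

    def predict_scores(self, X):
        return predict_forest(self.ensemble, np.asarray(X, float)[:, self.keep])


def _make_adapter(name: str, sampler_config: SamplerConfig):
    if name == "lda":
        return _LdaAdapter()
    if name == "forest":
        return _ForestAdapter(sampler_config)
    raise ValueError(f"unknown classifier {name!r}")


# ---------------------------------------------------------------------------
# Severity pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridChoice:
    dsr_s: float
    m: int
    r: float

    def key(self):
        return (self.dsr_s, self.m, self.r)


@dataclass
class SeverityConfig:
    dsr_values: tuple = DSR_GRID
    m_values: tuple = mse.M_GRID
    r_values: tuple = mse.R_GRID
    scales: tuple = mse.DEFAULT_SCALES
    k_folds: int = 5
    inner_splits: int = 5
    val_fraction: float = 0.30
    classifier_names: tuple = ("lda", "forest")
    feature_sets: tuple = ("mse", "mse+demos")
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    #: lighter sampler for the 5 x 96-combination inner loop
    sampler_grid: SamplerConfig = field(default_factory=lambda: SamplerConfig(
        n_trees=25, n_iterations=2000, n_restarts=1, thin_interval=200))
    seed: int = 0
    start_offset_s: float = 1800.0
    analysis_duration_s: float = 14400.0
    envelope_eps: float = 1e-12
    threshold: float = 0.5


def subject_entropy_tables(bundle: CohortBundle, config: SeverityConfig) -> dict:
    """Per-subject, per-dsr entropy tables of shape (|m|, |r|, |scales|).

    Envelope-mode bundles supply envelopes at a single dsr; audio-mode
    bundles are windowed and enveloped at every configured dsr.
    """
    tables = {}
    if bundle.envelopes:
        dsrs = (bundle.envelope_dsr_s,)
        for sid, envs in bundle.envelopes.items():
            tables[sid] = {bundle.envelope_dsr_s: mse.entropy_table(
                envs[bundle.envelope_dsr_s], config.m_values, config.r_values,
                config.scales)}
    else:
        dsrs = config.dsr_values
        for sid, rec in bundle.audio.items():
            seg = extract_analysis_window(rec, config.start_offset_s,
                                          config.analysis_duration_s)
            tables[sid] = {}
            for dsr in dsrs:
                env = log_variance_envelope(seg, rec.fs, dsr,
                                            config.envelope_eps, sid)
                tables[sid][dsr] = mse.entropy_table(
                    env.values, config.m_values, config.r_values, config.scales)
    return tables


def _combo_features(tables, subjects, combo: GridChoice, config: SeverityConfig,
                    demos: np.ndarray | None = None,
                    subject_index: dict | None = None) -> np.ndarray:
    mi = config.m_values.index(combo.m)
    ri = config.r_values.index(combo.r)
    X = np.vstack([tables[s][combo.dsr_s][mi, ri, :] for s in subjects])
    if demos is not None:
        rows = [subject_index[s] for s in subjects]
        X = np.hstack([X, demos[rows]])
    return X


def _stratified_split(subjects, labels, val_fraction, rng):
    """Random subject-level split preserving the class mix (70:30 default)."""
    subjects = np.asarray(subjects)
    labels = np.asarray(labels, dtype=int)
    val = []
    for cls in (0, 1):
        members = subjects[labels == cls]
        n_val = max(1, int(round(val_fraction * members.shape[0])))
        val.extend(rng.permutation(members)[:n_val].tolist())
    val = set(val)
    train = [s for s in subjects if s not in val]
    return train, sorted(val)


def grid_search_mse_params(tables, subjects, labels_by_subject,
                           config: SeverityConfig, classifier: str,
                           seed: int) -> GridChoice:
    """Modal best (dsr, m, r) over five stratified 70:30 train/validation splits.

    Each split scores every grid combination by validation accuracy; ties
    across splits break by mean validation accuracy, then by the smallest
    (dsr, m, r) lexicographically.
    """
    dsrs = [d for d in config.dsr_values
            if all(d in tables[s] for s in subjects)]
    combos = [GridChoice(d, m, r) for d, m, r in
              itertools.product(dsrs, config.m_values, config.r_values)]
    labels = np.asarray([labels_by_subject[s] for s in subjects], dtype=int)
    rng = np.random.default_rng(seed)
    wins = {c.key(): 0 for c in combos}
    acc_sums = {c.key(): 0.0 for c in combos}
    for _ in range(config.inner_splits):
        tr, va = _stratified_split(subjects, labels, config.val_fraction, rng)
        y_tr = np.asarray([labels_by_subject[s] for s in tr], dtype=int)
        y_va = np.asarray([labels_by_subject[s] for s in va], dtype=int)
        best_acc, best_combo = -1.0, None
        for c in combos:
            X_tr = _combo_features(tables, tr, c, config)
            X_va = _combo_features(tables, va, c, config)
            try:
                adapter = _make_adapter(classifier, config.sampler_grid)
                adapter.fit(X_tr, y_tr)
                scores = adapter.predict_scores(X_va)
            except ValueError:
                continue
            acc = float(np.mean((scores >= config.threshold).astype(int) == y_va))
            acc_sums[c.key()] += acc
            if acc > best_acc:
                best_acc, best_combo = acc, c
        if best_combo is not None:
            wins[best_combo.key()] += 1
    best = max(combos, key=lambda c: (wins[c.key()], acc_sums[c.key()],
                                      tuple(-v for v in c.key())))
    return best


def run_severity_pipeline(bundle: CohortBundle, config: SeverityConfig,
                          tables: dict | None = None):
    """Nested-CV severity classification; returns (summary, per-fold detail).

    summary: one row per (classifier, feature_set) with mean and SD of each
    metric across outer folds plus the per-fold grid choices.
    """
    meta = bundle.metadata
    subjects = meta["subject_id"].tolist()
    labels_by_subject = dict(zip(meta["subject_id"], meta["label"].astype(int)))
    if tables is None:
        tables = subject_entropy_tables(bundle, config)
    demo_cols = ["gender", "age", "neck", "height", "weight", "bmi", "ess"]
    demos = np.column_stack([
        (meta["gender"] == "m").astype(float).to_numpy()
        if c == "gender" else meta[c].to_numpy(float) for c in demo_cols])
    subject_index = {s: i for i, s in enumerate(subjects)}

    plan = stratified_subject_folds(subjects,
                                    [labels_by_subject[s] for s in subjects],
                                    config.k_folds, config.seed)
    fold_rows = []
    for fold in range(config.k_folds):
        tr = plan.train_subjects(fold)
        te = plan.fold_subjects(fold)
        assert not set(tr) & set(te), "subject leakage between train and test"
        y_tr = np.asarray([labels_by_subject[s] for s in tr], dtype=int)
        y_te = np.asarray([labels_by_subject[s] for s in te], dtype=int)
        for clf in config.classifier_names:
            choice = grid_search_mse_params(
                tables, tr, labels_by_subject, config, clf,
                seed=int(np.random.default_rng([config.seed, fold]).integers(2 ** 31)))
            for fs in config.feature_sets:
                use_demos = fs.endswith("demos")
                kw = dict(demos=demos if use_demos else None,
                          subject_index=subject_index if use_demos else None)
                X_tr = _combo_features(tables, tr, choice, config, **kw)
                X_te = _combo_features(tables, te, choice, config, **kw)
                adapter = _make_adapter(clf, config.sampler)
                adapter.fit(X_tr, y_tr)
                m = compute_metrics(adapter.predict_scores(X_te), y_te,
                                    config.threshold)
                fold_rows.append(dict(fold=fold, classifier=clf,
                                      feature_set=fs, dsr_s=choice.dsr_s,
                                      m=choice.m, r=choice.r, **m.as_dict()))
        logger.info("severity fold %d done", fold)
    detail = pd.DataFrame(fold_rows)
    summary = (detail.groupby(["classifier", "feature_set"])[list(METRIC_NAMES)]
               .agg(["mean", "std"]))
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    return summary.reset_index(), detail


# ---------------------------------------------------------------------------
# Event pipeline
# ---------------------------------------------------------------------------

@dataclass
class EventConfig:
    windows: tuple = EVENT_WINDOWS
    feature_sets: tuple = ("L", "C", "LC", "LD", "CD", "LCD")
    k_folds: int = 5
    seed: int = 0
    threshold: float = 0.5


def _demographics_from_metadata(meta: pd.DataFrame) -> dict:
    out = {}
    for r in meta.itertuples():
        out[r.subject_id] = Demographics(
            gender=str(r.gender), age=float(r.age), neck=float(r.neck),
            height=float(r.height), bmi=float(r.bmi), weight=float(r.weight),
            ess=int(r.ess))
    return out


def run_event_pipeline(bundle: CohortBundle, config: EventConfig):
    """F vs S/N classification with LDA; returns (summary, survivor counts).

    summary: per (window, feature_set) mean and SD of each metric over
    subject-stratified folds.  survivors: per (window, class) event counts
    after the exclusion rule.
    """
    meta = bundle.metadata
    demos = _demographics_from_metadata(meta)
    subjects = meta["subject_id"].tolist()
    rows, surv_rows = [], []
    for w in config.windows:
        windows, counts = [], {"F": 0, "S": 0, "N": 0}
        for sid in subjects:
            inc, c = clip_events(bundle.annotations.get(sid, []),
                                 bundle.audio[sid], w)
            windows.extend(inc)
            for k, v in c.items():
                counts[k] = counts.get(k, 0) + v
        for k in ("F", "S", "N"):
            surv_rows.append(dict(window_s=w, event_class=k, count=counts[k]))
        if not windows:
            continue
        # Subject-level stratification label: has at least one surviving F.
        has_f = {sid: 0 for sid in subjects}
        for win in windows:
            if win.event_class == "F":
                has_f[win.subject_id] = 1
        used = sorted({win.subject_id for win in windows})
        strat = [has_f[s] for s in used]
        if len(used) < config.k_folds:
            logger.warning("window %.1fs: fewer subjects than folds; skipped", w)
            continue
        if len(set(strat)) < 2:
            # all subjects share the stratum (e.g. every subject has an F
            # event): plain shuffled round-robin partition
            rng = np.random.default_rng(config.seed)
            order = rng.permutation(len(used))
            plan = FoldPlan(k=config.k_folds,
                            assignments={used[i]: pos % config.k_folds
                                         for pos, i in enumerate(order)},
                            seed=config.seed)
        else:
            plan = stratified_subject_folds(used, strat, config.k_folds,
                                            config.seed)
        ev_sid = np.asarray([win.subject_id for win in windows])
        # compute all three blocks once; feature sets are column slices
        X_all, y, sids, cols = build_event_features(windows, {"L", "C", "D"},
                                                    demos)
        block_cols = {"L": [c for c in cols if c.startswith("lpc_")],
                      "C": [c for c in cols if c.startswith("mfcc_")],
                      "D": [c for c in cols if not c.startswith(("lpc_", "mfcc_"))]}
        col_index = {c: i for i, c in enumerate(cols)}
        for fs in config.feature_sets:
            take = [col_index[c] for b in "LCD" if b in fs
                    for c in block_cols[b]]
            X = X_all[:, take]
            fold_metrics = []
            for fold in range(config.k_folds):
                te_set = set(plan.fold_subjects(fold))
                te_mask = np.isin(ev_sid, list(te_set))
                tr_mask = ~te_mask
                if len(np.unique(y[tr_mask])) < 2 or te_mask.sum() == 0:
                    logger.warning("window %.1fs %s fold %d lost a class",
                                   w, fs, fold)
                    fold_metrics.append(Metrics(*([float("nan")] * 6)))
                    continue
                # adapter drops degenerate columns (e.g. a demographic
                # constant across the training subjects of a fold)
                adapter = _LdaAdapter().fit(X[tr_mask], y[tr_mask])
                scores = adapter.predict_scores(X[te_mask])
                fold_metrics.append(compute_metrics(scores, y[te_mask],
                                                    config.threshold))
            arr = {m: np.asarray([getattr(fm, m) for fm in fold_metrics])
                   for m in METRIC_NAMES}
            row = dict(window_s=w, feature_set=fs)
            for m in METRIC_NAMES:
                row[f"{m}_mean"] = float(np.mean(arr[m]))
                row[f"{m}_std"] = float(np.std(arr[m], ddof=1))
            rows.append(row)
        logger.info("event window %.1fs done", w)
    return pd.DataFrame(rows), pd.DataFrame(surv_rows)
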