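"""Fold construction, metric arithmetic, grid search, and pipeline behaviour."""

import numpy as np
import pandas as pd
import pytest

from osascreen import synthetic as syn
from osascreen.classifiers import SamplerConfig
from osascreen.evaluation import (EventConfig, GridChoice, SeverityConfig,
                                  clinical_baseline, compute_metrics,
                                  grid_search_mse_params, rank_auc,
                                  run_event_pipeline, run_severity_pipeline,
                                  stratified_subject_folds,
                                  subject_entropy_tables, threshold_classifier)


class TestFolds:
    def _plan(self, n=23, k=5, seed=0):
        sids = [f"S{i:03d}" for i in range(n)]
        labels = [i % 3 == 0 for i in range(n)]
        return sids, np.asarray(labels, int), stratified_subject_folds(
            sids, labels, k, seed)

    def test_partition_covers_all_subjects_once(self):
        sids, _, plan = self._plan()
        seen = [s for f in range(5) for s in plan.fold_subjects(f)]
        assert sorted(seen) == sorted(sids)

    def test_fold_sizes_within_one(self):
        _, _, plan = self._plan()
        sizes = [len(plan.fold_subjects(f)) for f in range(5)]
        assert max(sizes) - min(sizes) <= 1

    def test_class_mix_balanced(self):
        sids, labels, plan = self._plan(n=40, k=5)
        lab = dict(zip(sids, labels))
        pos_counts = [sum(lab[s] for s in plan.fold_subjects(f))
                      for f in range(5)]
        assert max(pos_counts) - min(pos_counts) <= 1

    def test_train_and_test_disjoint(self):
        _, _, plan = self._plan()
        for f in range(5):
            assert not set(plan.fold_subjects(f)) & set(plan.train_subjects(f))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_subject_folds(["a", "b", "c"], [1, 1, 1], 2, 0)

    def test_more_folds_than_subjects_rejected(self):
        with pytest.raises(ValueError):
            stratified_subject_folds(["a", "b"], [0, 1], 3, 0)


class TestMetrics:
    def test_hand_computed_confusion(self):
        """4 positives (3 detected), 6 negatives (5 rejected)."""
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        scores = [0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.1, 0.2, 0.3, 0.4]
        m = compute_metrics(scores, labels)
        assert m.se == pytest.approx(75.0)
        assert m.sp == pytest.approx(100 * 5 / 6)
        assert m.ppv == pytest.approx(75.0)
        assert m.npv == pytest.approx(100 * 5 / 6)
        assert m.ac == pytest.approx(80.0)

    def test_accuracy_identity(self):
        """Ac = (Se*P + Sp*N) / (P + N) whenever Se and Sp are defined."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            labels = rng.integers(0, 2, 30)
            if len(set(labels)) < 2:
                continue
            scores = rng.random(30)
            m = compute_metrics(scores, labels)
            p, n = labels.sum(), (1 - labels).sum()
            assert m.ac == pytest.approx((m.se * p + m.sp * n) / (p + n))

    def test_ppv_nan_when_no_positive_predictions(self):
        m = compute_metrics([0.1, 0.2, 0.3], [0, 1, 0])
        assert np.isnan(m.ppv) and m.se == 0.0

    def test_auc_perfect_separation(self):
        assert rank_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        s = rng.random(50)
        y = rng.integers(0, 2, 50)
        assert rank_auc(s, y) == pytest.approx(rank_auc(np.exp(3 * s), y))

    def test_auc_ties_count_half(self):
        assert rank_auc([0.5, 0.5], [0, 1]) == 0.5

    def test_auc_nan_single_class(self):
        assert np.isnan(rank_auc([0.1, 0.9], [1, 1]))

    def test_threshold_classifier_boundary_inclusive(self):
        assert threshold_classifier([4.9, 5.0, 5.1], 5.0).tolist() == [0, 1, 1]

    def test_clinical_baseline_rows_and_ahi15_perfect(self):
        meta = pd.DataFrame({
            "subject_id": ["a", "b", "c", "d"],
            "gender": ["m", "f", "m", "f"],
            "age": [60.0, 30.0, 55.0, 40.0],
            "neck": [44.0, 36.0, 42.0, 37.0],
            "bmi": [38.0, 24.0, 36.0, 26.0],
            "ess": [18, 6, 16, 5],
            "true_ahi": [40.0, 2.0, 25.0, 4.0],
            "label": [1, 0, 1, 0]})
        df = clinical_baseline(meta)
        row = df[(df.feature == "true_ahi") & (df.threshold == 15.0)].iloc[0]
        assert row.se == 100.0 and row.sp == 100.0
        assert set(df.feature) == {"gender", "age", "neck", "bmi", "ess",
                                   "true_ahi"}


def _toy_tables(n, seed, config):
    """Severity-like toy problem: a single (m, r, scale) cell carries the
    signal (higher for positives), everything else is noise."""
    rng = np.random.default_rng(seed)
    sids = [f"S{i:03d}" for i in range(n)]
    labels = {s: int(i < n // 2) for i, s in enumerate(sids)}
    tables = {}
    shape = (len(config.m_values), len(config.r_values), len(config.scales))
    for s in sids:
        t = rng.normal(0.0, 1.0, shape)
        if labels[s]:
            t[0, 0, :] += 4.0  # signal at m=1, r=first grid value
        tables[s] = {1.0: t}
    return sids, labels, tables


class TestGridSearch:
    def _config(self):
        return SeverityConfig(dsr_values=(1.0,), m_values=(1, 2, 3),
                              r_values=(0.10, 0.20), inner_splits=5)

    def test_finds_informative_cell(self):
        cfg = self._config()
        sids, labels, tables = _toy_tables(30, 3, cfg)
        choice = grid_search_mse_params(tables, sids, labels, cfg, "lda", 7)
        assert (choice.m, choice.r) == (1, 0.10)

    def test_deterministic(self):
        cfg = self._config()
        sids, labels, tables = _toy_tables(30, 4, cfg)
        c1 = grid_search_mse_params(tables, sids, labels, cfg, "lda", 7)
        c2 = grid_search_mse_params(tables, sids, labels, cfg, "lda", 7)
        assert c1 == c2

    def test_tie_break_prefers_smallest_key(self):
        """With no signal anywhere, ties resolve toward the lexicographically
        smallest (dsr, m, r) among equally-scoring combinations."""
        cfg = self._config()
        rng = np.random.default_rng(5)
        sids = [f"S{i}" for i in range(12)]
        labels = {s: int(i < 6) for i, s in enumerate(sids)}
        shape = (3, 2, len(cfg.scales))
        tables = {s: {1.0: np.zeros(shape) + rng.normal() * 0 + i * 0.0 + 1.0}
                  for i, s in enumerate(sids)}
        # identical constant tables -> LDA rejects (zero variance); every
        # combination scores zero wins and the smallest key must win
        choice = grid_search_mse_params(tables, sids, labels, cfg, "lda", 9)
        assert choice == GridChoice(1.0, 1, 0.10)


@pytest.fixture(scope="module")
def severity_run():
    bundle = syn.generate_cohort(
        20, 3600.0, seed=11, mode="envelope",
        severity_mix={"normal": 0.5, "severe": 0.5})
    cfg = SeverityConfig(
        dsr_values=(1.0,), m_values=(1, 2), r_values=(0.10, 0.20),
        scales=(1, 2, 4, 8, 16, 32), inner_splits=3,
        classifier_names=("lda",), seed=5)
    summary, detail = run_severity_pipeline(bundle, cfg)
    return bundle, cfg, summary, detail


@pytest.fixture(scope="module")
def event_run():
    bundle = syn.generate_cohort(
        6, 900.0, seed=21, mode="audio", fs=2000.0,
        severity_mix={"severe": 1.0})
    cfg = EventConfig(windows=(1.0, 2.0), feature_sets=("L", "LC"), seed=3)
    summary, survivors = run_event_pipeline(bundle, cfg)
    return bundle, cfg, summary, survivors


class TestSeverityPipeline:

    def test_summary_shape_and_contents(self, severity_run):
        _, cfg, summary, detail = severity_run
        assert set(summary["classifier"]) == {"lda"}
        assert set(summary["feature_set"]) == {"mse", "mse+demos"}
        assert len(detail) == cfg.k_folds * len(cfg.feature_sets)
        assert detail["m"].isin(cfg.m_values).all()
        assert detail["r"].isin(cfg.r_values).all()

    def test_separable_cohort_classified_well(self, severity_run):
        """Normal vs severe on synthetic envelopes is nearly separable."""
        _, _, summary, _ = severity_run
        row = summary[summary.feature_set == "mse"].iloc[0]
        assert row["auc_mean"] >= 0.9
        assert row["ac_mean"] >= 80.0

    def test_deterministic_given_seed(self, severity_run):
        bundle, cfg, _, detail = severity_run
        _, detail2 = run_severity_pipeline(bundle, cfg)
        pd.testing.assert_frame_equal(detail, detail2)

    def test_shuffled_labels_destroy_signal(self, severity_run):
        """Permuted labels: accuracy falls to chance level."""
        bundle, cfg, _, _ = severity_run
        meta = bundle.metadata.copy()
        rng = np.random.default_rng(13)
        meta["label"] = rng.permutation(meta["label"].to_numpy())
        shuffled = syn.CohortBundle(
            metadata=meta, audio=bundle.audio, annotations=bundle.annotations,
            envelopes=bundle.envelopes, envelope_dsr_s=bundle.envelope_dsr_s,
            outdir=bundle.outdir)
        summary, _ = run_severity_pipeline(shuffled, cfg)
        row = summary[summary.feature_set == "mse"].iloc[0]
        assert row["ac_mean"] < 75.0

    def test_precomputed_tables_reused(self, severity_run):
        bundle, cfg, _, detail = severity_run
        tables = subject_entropy_tables(bundle, cfg)
        _, detail2 = run_severity_pipeline(bundle, cfg, tables=tables)
        pd.testing.assert_frame_equal(detail, detail2)


class TestEventPipeline:
    def test_survivor_counts_non_increasing(self, event_run):
        _, _, _, survivors = event_run
        for cls in ("F", "S", "N"):
            c = survivors[survivors.event_class == cls].sort_values("window_s")
            counts = c["count"].tolist()
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_summary_rows_per_window_and_feature_set(self, event_run):
        _, cfg, summary, _ = event_run
        assert len(summary) == len(cfg.windows) * len(cfg.feature_sets)
        assert set(summary.feature_set) == set(cfg.feature_sets)

    def test_metrics_within_percent_bounds(self, event_run):
        _, _, summary, _ = event_run
        vals = summary[["se_mean", "sp_mean", "ac_mean"]].to_numpy(float)
        finite = vals[np.isfinite(vals)]
        assert ((finite >= 0) & (finite <= 100)).all()

    def test_deterministic(self, event_run):
        bundle, cfg, summary, survivors = event_run
        s2, v2 = run_event_pipeline(bundle, cfg)
        pd.testing.assert_frame_equal(summary, s2)
        pd.testing.assert_frame_equal(survivors, v2)
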