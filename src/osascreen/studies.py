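"""Canonical synthetic-cohort study runs.

These are the two headline analyses at the problem sizes this package runs
by default, shared by the analysis drivers and the acceptance script:

* severity study — 60 subjects (30 severe with AHI >= 30, 30 normal with
  AHI < 5), 240-minute log-variance envelopes at dsr = 1 s (envelope-only
  fast mode), nested cross-validation with grid search over (m, r).
* event study — 10 severe subjects, 30 minutes each, full 4 kHz audio with
  F/S/N annotations (several hundred events per class), LDA classification
  of choke vs snore/noise over all window sizes and feature sets.
"""

from __future__ import annotations

import numpy as np

from .evaluation import (EventConfig, SeverityConfig, run_event_pipeline,
                         run_severity_pipeline)
from .synthetic import GeneratorConfig, generate_cohort


def severity_study(seed: int, n_subjects: int = 60,
                   classifier_names=("forest", "lda"),
                   duration_s: float = 14400.0, dsr_s: float = 1.0):
    """Severity arm on a normal-vs-severe envelope cohort.

    Returns (summary, detail, bundle); summary has mean/SD of each metric
    over the five outer folds per (classifier, feature set).
    """
    bundle = generate_cohort(n_subjects=n_subjects, duration_s=duration_s,
                             seed=seed,
                             severity_mix={"normal": 0.5, "severe": 0.5},
                             mode="envelope", dsr_s=dsr_s)
    config = SeverityConfig(classifier_names=tuple(classifier_names),
                            seed=seed)
    summary, detail = run_severity_pipeline(bundle, config)
    return summary, detail, bundle


def event_study(seed: int, n_subjects: int = 10, duration_s: float = 1800.0):
    """Event arm on an annotated all-severe audio cohort.

    The noise-event rate is raised to the snore-rate scale so the three
    annotation classes are comparably sized (F : S+N near 1:2).
    Returns (summary, survivors, bundle).
    """
    gen_cfg = GeneratorConfig(noise_rate_per_h=45.0)
    bundle = generate_cohort(n_subjects=n_subjects, duration_s=duration_s,
                             seed=seed, severity_mix={"severe": 1.0},
                             mode="audio", cfg=gen_cfg)
    summary, survivors = run_event_pipeline(bundle, EventConfig(seed=seed))
    return summary, survivors, bundle


def seeded(seed: int, salt: int) -> int:
    """Deterministic sub-seed below 2**31."""
    return int(np.random.default_rng([seed, salt]).integers(2 ** 31))
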