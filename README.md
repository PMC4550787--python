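# osascreen

Audio-only screening for obstructive sleep apnea (OSA), evaluated
end-to-end on a synthetic overnight cohort.

The package implements two complementary analysis arms over overnight
audio:

* **Severity arm** — the log-variance envelope of a 240-minute audio
  window is summarised by **multiscale entropy** (sample entropy
  `H_s = −ln(A/B)` on coarse-grained series, Chebyshev distance,
  tolerance `r·σ` anchored at scale 1), and the per-subject entropy
  profile — optionally with demographics — is classified as
  `AHI >= 15` vs below with either a pooled-diagonal-covariance **LDA**
  or an **MCMC-sampled forest** of two-split trees with linear leaf
  contributions. Model selection over `(dsr, m, r)` runs as a nested
  grid search inside subject-stratified 5-fold cross-validation.
* **Event arm** — annotated short events (F = first breath after apnea,
  S = snore, N = noise) are clipped to fixed windows (0.5–3 s) and
  classified F vs S/N by LDA on **LPC-8** and **MFCC c1..c12**
  features, optionally with demographics.

Because no clinical recordings ship with the package, a **synthetic
cohort generator** produces audio (or envelope-only fast-mode) cohorts
whose demographics match published OSA clinic group statistics and whose
apnea/snore/noise event structure follows each subject's sampled AHI.
See `docs/methods.md` for the full model and its limitations.

## Worked example

```python
import numpy as np
from osascreen import mse, synthetic, preprocess

# one severe subject, 1 hour of envelope-mode data at dsr = 1 s
profile = synthetic.make_profiles(2, {"severe": 1.0}, seed=7)[0]
env, events = synthetic.generate_subject_envelope(profile, 3600.0, 1.0)

params = mse.MSEParams(scales=(1, 2, 4, 8, 16, 32), m=2, r=0.15)
print(mse.mse_profile(env, params).entropies.round(3))
```

prints the six-scale entropy profile of that subject's envelope, e.g.
higher values at long scales for apneic subjects than for normal
sleepers (the severity feature).

A small end-to-end run:

```python
from osascreen.studies import severity_study
summary, detail, bundle = severity_study(seed=1, n_subjects=20,
                                         classifier_names=("lda",))
print(summary[["classifier", "feature_set", "ac_mean", "auc_mean"]])
```

## Layout

```
src/osascreen/      mse, preprocess, event_features, classifiers,
                    evaluation, synthetic, studies
analysis/           numbered result-producing drivers
scripts/acceptance.py   headline-study summary as JSON
tests/              property-based and end-to-end tests
docs/methods.md     model, numerical choices, limitations
```
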