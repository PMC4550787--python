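"""Synthetic overnight-audio cohort generator.

The real study data (858 overnight recordings from a sleep clinic) is not
public, so every downstream stage is exercised on a synthetic cohort that
reproduces the statistical structure the analysis assumes:

* a breathing base — band-limited noise amplitude-modulated at the
  respiratory rate (~0.2–0.3 Hz);
* snore (S) events — harmonic-rich bursts locked to breathing peaks, at a
  per-severity rate;
* apnea episodes at ``true_ahi`` per hour — near-silent gaps of 10–60 s,
  each terminated by a loud broadband choke / first-breath (F) burst;
* noise (N) events — random transients (clicks, beeps, noise bursts);
* per-severity demographics drawn from the published group statistics.

Two rendering modes share one event schedule: full 4 kHz audio, and an
"envelope-only" fast mode that emits the log-variance envelope directly
(same amplitude structure, no audio synthesis) for cheap end-to-end runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.io import wavfile

SEVERITIES = ("normal", "snorer", "mild", "moderate", "severe")

#: AHI bands (events/h) per severity group: normal/snorer < 5, mild 5–15,
#: moderate 15–30, severe >= 30.
AHI_BANDS = {
    "normal": (0.0, 5.0),
    "snorer": (0.0, 5.0),
    "mild": (5.0, 15.0),
    "moderate": (15.0, 30.0),
    "severe": (30.0, 100.0),
}

#: Published per-group statistics (mean, SD) and male fraction for the five
#: severity groups, with group sizes used for the default cohort mix.
GROUP_STATS = {
    "normal": dict(n=155, male_frac=80 / 155, age=(45.9, 17.1),
                   neck=(39.4, 4.6), height=(171.2, 10.7), bmi=(29.6, 7.9),
                   ess=(11.0, 5.6), ahi=(4.4, 7.5)),
    "snorer": dict(n=257, male_frac=166 / 257, age=(46.5, 12.0),
                   neck=(41.4, 4.3), height=(173.5, 10.4), bmi=(32.0, 8.4),
                   ess=(12.0, 5.2), ahi=(6.4, 7.4)),
    "mild": dict(n=107, male_frac=79 / 107, age=(50.5, 11.4),
                 neck=(41.9, 4.1), height=(174.2, 9.9), bmi=(31.9, 7.9),
                 ess=(12.2, 4.7), ahi=(10.6, 9.0)),
    "moderate": dict(n=124, male_frac=94 / 124, age=(53.1, 12.4),
                     neck=(42.9, 3.8), height=(173.0, 9.7), bmi=(33.8, 8.5),
                     ess=(12.7, 4.7), ahi=(21.5, 11.6)),
    "severe": dict(n=215, male_frac=167 / 215, age=(52.5, 12.6),
                   neck=(45.0, 4.8), height=(175.0, 9.1), bmi=(36.9, 11.2),
                   ess=(14.1, 5.3), ahi=(47.5, 24.5)),
}

#: Default severity mix: proportional to the published group sizes.
DEFAULT_SEVERITY_MIX = {g: GROUP_STATS[g]["n"] / 858 for g in SEVERITIES}

#: Physiologic truncation ranges for demographic sampling.
PHYSIOLOGIC_RANGES = {
    "age": (18.0, 95.0),
    "neck": (25.0, 60.0),
    "height": (140.0, 210.0),
    "bmi": (15.0, 70.0),
    "ess": (0.0, 24.0),
}

#: Treatment-requiring threshold on the apnea–hypopnea index.
AHI_LABEL_THRESHOLD = 15.0


@dataclass(frozen=True)
class Demographics:
    gender: str  # "m" or "f"
    age: float   # years
    neck: float  # cm
    height: float  # cm
    bmi: float   # kg/m^2
    weight: float  # kg, derived: bmi * (height/100)^2
    ess: int     # Epworth Sleepiness Scale, 0–24

    def as_vector(self) -> np.ndarray:
        """Numeric feature block (gender m=1/f=0, age, neck, height, weight, bmi, ess)."""
        return np.array([1.0 if self.gender == "m" else 0.0, self.age,
                         self.neck, self.height, self.weight, self.bmi,
                         float(self.ess)])


DEMOGRAPHIC_FEATURE_NAMES = ("gender", "age", "neck", "height", "weight",
                             "bmi", "ess")


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    severity: str
    true_ahi: float
    demographics: Demographics
    seed: int

    def __post_init__(self):
        lo, hi = AHI_BANDS[self.severity]
        if not (lo <= self.true_ahi < hi or (self.severity == "severe"
                                             and self.true_ahi >= lo)):
            raise ValueError(
                f"true_ahi={self.true_ahi} outside {self.severity} band {(lo, hi)}")


@dataclass(frozen=True)
class EventAnnotation:
    event_class: str  # "F", "S" or "N"
    start_s: float
    duration_s: float

    def __post_init__(self):
        if self.event_class not in ("F", "S", "N"):
            raise ValueError(f"unknown event class {self.event_class!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")


@dataclass
class AudioRecording:
    samples: np.ndarray
    fs: float
    subject_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable acoustics of the synthetic recordings.

    Amplitudes are relative to the breathing peak; rates are events/hour.
    """

    breathing_rate_range: tuple = (0.2, 0.3)   # Hz
    breath_amplitude: float = 0.12             # full-scale units at breath peak
    breath_floor: float = 0.10                 # min breathing modulation (fraction)
    ambient_noise: float = 0.004               # microphone/room noise floor
    apnea_gap_fraction: float = 0.02           # residual amplitude inside a gap
    apnea_gap_range_s: tuple = (10.0, 60.0)
    f_burst_duration_range_s: tuple = (1.0, 6.0)
    f_burst_gain: float = 5.0
    snore_gain: float = 3.0
    snore_duration_range_s: tuple = (1.0, 12.0)  # annotated snore trains
    snore_f0_range_hz: tuple = (60.0, 180.0)
    noise_gain: float = 2.0
    noise_duration_range_s: tuple = (0.5, 15.0)  # annotated noise stretches
    snore_rate_per_h: dict = field(default_factory=lambda: {
        "normal": 6.0, "snorer": 90.0, "mild": 60.0,
        "moderate": 50.0, "severe": 45.0})
    noise_rate_per_h: float = 20.0
    envelope_jitter_sd: float = 0.10           # log-variance texture noise


def assign_label(ahi: float) -> int:
    """1 (treatment-requiring: moderate/severe) iff AHI >= 15, else 0."""
    if ahi < 0:
        raise ValueError("AHI must be non-negative")
    return int(ahi >= AHI_LABEL_THRESHOLD)


def _trunc_normal(mean, sd, lo, hi, rng, max_z: float = 4.0):
    """Normal draw truncated symmetrically about the mean.

    The truncation window is the widest symmetric interval around the mean
    that fits inside [lo, hi] (capped at ±max_z SDs), so truncation never
    biases the group mean.
    """
    if sd == 0:
        return float(mean)
    half = min(mean - lo, hi - mean, max_z * sd)
    if half <= 0:
        raise ValueError(f"mean {mean} outside physiologic range [{lo}, {hi}]")
    a = -half / sd
    return float(stats.truncnorm.rvs(a, -a, loc=mean, scale=sd, random_state=rng))


def sample_demographics(severity: str, rng: np.random.Generator,
                        stats_table: dict | None = None) -> Demographics:
    """Draw one subject's demographics from the group's truncated normals.

    Weight is derived from the sampled BMI and height rather than drawn,
    keeping the three fields mutually consistent.
    """
    table = stats_table or GROUP_STATS
    if severity not in table:
        raise ValueError(f"unknown severity {severity!r}")
    g = table[severity]
    gender = "m" if rng.random() < g["male_frac"] else "f"
    age = _trunc_normal(*g["age"], *PHYSIOLOGIC_RANGES["age"], rng)
    neck = _trunc_normal(*g["neck"], *PHYSIOLOGIC_RANGES["neck"], rng)
    height = _trunc_normal(*g["height"], *PHYSIOLOGIC_RANGES["height"], rng)
    bmi = _trunc_normal(*g["bmi"], *PHYSIOLOGIC_RANGES["bmi"], rng)
    ess = int(round(_trunc_normal(*g["ess"], *PHYSIOLOGIC_RANGES["ess"], rng)))
    weight = bmi * (height / 100.0) ** 2
    return Demographics(gender=gender, age=age, neck=neck, height=height,
                        bmi=bmi, weight=weight, ess=ess)


def sample_ahi(severity: str, rng: np.random.Generator) -> float:
    """AHI drawn from the group's published distribution, truncated to its band.

    Band truncation is deliberately asymmetric (e.g. the normal group's
    published mean sits near the top of its 0–5 band), so the realized group
    mean can differ from the published one; the severity bands take priority.
    """
    lo, hi = AHI_BANDS[severity]
    mean, sd = GROUP_STATS[severity]["ahi"]
    a, b = (lo - mean) / sd, (hi - 1e-9 - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


# ---------------------------------------------------------------------------
# Event scheduling (shared by the audio and envelope renderers)
# ---------------------------------------------------------------------------

@dataclass
class _Schedule:
    breathing_rate_hz: float
    events: list            # EventAnnotation, sorted by start
    apnea_gaps: list        # (gap_start_s, gap_end_s) per apnea
    snore_f0: dict          # event index -> fundamental (Hz)
    noise_kind: dict        # event index -> "click" | "beep" | "burst"


def _overlaps(intervals, start, end, pad=0.25):
    return any(start < e + pad and end > s - pad for s, e in intervals)


def _build_schedule(profile: SubjectProfile, duration_s: float,
                    rng: np.random.Generator,
                    cfg: GeneratorConfig) -> _Schedule:
    hours = duration_s / 3600.0
    f_b = rng.uniform(*cfg.breathing_rate_range)
    events, gaps, occupied = [], [], []
    snore_f0, noise_kind = {}, {}

    # Apneas: one per equal block so the realized hourly rate tracks true_ahi.
    n_apnea = int(round(profile.true_ahi * hours))
    if n_apnea > 0:
        block = duration_s / n_apnea
        for k in range(n_apnea):
            g_lo, g_hi = cfg.apnea_gap_range_s
            g_hi = min(g_hi, 0.6 * block)
            if g_hi <= g_lo:
                g_hi = g_lo + 1.0
            gap = rng.uniform(g_lo, g_hi)
            f_dur = rng.uniform(*cfg.f_burst_duration_range_s)
            lo = k * block + 1.0
            hi = (k + 1) * block - gap - f_dur - 1.0
            if hi <= lo:
                continue
            gs = rng.uniform(lo, hi)
            gaps.append((gs, gs + gap))
            events.append(EventAnnotation("F", round(gs + gap, 3),
                                          round(f_dur, 3)))
            occupied.append((gs, gs + gap + f_dur))

    # Snores: drawn from breathing-peak times outside occupied stretches.
    rate = cfg.snore_rate_per_h.get(profile.severity, 0.0)
    n_snore = rng.poisson(rate * hours)
    if n_snore > 0:
        peaks = (np.arange(int(duration_s * f_b)) + 0.25) / f_b
        rng.shuffle(peaks)
        placed = 0
        for t in peaks:
            if placed >= n_snore:
                break
            dur = rng.uniform(*cfg.snore_duration_range_s)
            start = max(t - 0.2, 0.0)
            if start + dur > duration_s or _overlaps(occupied, start, start + dur):
                continue
            idx = len(events)
            events.append(EventAnnotation("S", round(start, 3), round(dur, 3)))
            snore_f0[idx] = rng.uniform(*cfg.snore_f0_range_hz)
            occupied.append((start, start + dur))
            placed += 1

    # Noise transients at uniform times.
    n_noise = rng.poisson(cfg.noise_rate_per_h * hours)
    tries = 0
    placed = 0
    while placed < n_noise and tries < 20 * max(n_noise, 1):
        tries += 1
        dur = rng.uniform(*cfg.noise_duration_range_s)
        start = rng.uniform(0.0, duration_s - dur)
        if _overlaps(occupied, start, start + dur):
            continue
        idx = len(events)
        events.append(EventAnnotation("N", round(start, 3), round(dur, 3)))
        noise_kind[idx] = ("click", "beep", "burst")[rng.integers(3)]
        occupied.append((start, start + dur))
        placed += 1

    order = np.argsort([e.start_s for e in events], kind="stable")
    ev_sorted, f0s, kinds = [], {}, {}
    for new_i, old_i in enumerate(order):
        ev_sorted.append(events[old_i])
        if old_i in snore_f0:
            f0s[new_i] = snore_f0[old_i]
        if old_i in noise_kind:
            kinds[new_i] = noise_kind[old_i]
    return _Schedule(breathing_rate_hz=f_b, events=ev_sorted,
                     apnea_gaps=gaps, snore_f0=f0s, noise_kind=kinds)


def _breath_modulation(t, f_b, cfg):
    base = (0.5 * (1.0 + np.sin(2.0 * np.pi * f_b * t))) ** 2
    return cfg.breath_floor + (1.0 - cfg.breath_floor) * base


def _bandpass_noise(n, fs, lo, hi, rng):
    hi = min(hi, 0.45 * fs)  # keep band inside Nyquist at low sampling rates
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_subject_audio(profile: SubjectProfile, duration_s: float,
                           fs: float = 4000.0,
                           rng: np.random.Generator | None = None,
                           cfg: GeneratorConfig | None = None,
                           ) -> tuple[AudioRecording, list]:
    """Render one subject's overnight audio and its F/S/N annotations."""
    if duration_s < 60:
        raise ValueError("duration_s must be >= 60")
    if fs < 2000:
        raise ValueError("fs must be >= 2000 Hz")
    cfg = cfg or GeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    sched = _build_schedule(profile, duration_s, rng, cfg)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    amp = cfg.breath_amplitude * _breath_modulation(t, sched.breathing_rate_hz, cfg)
    for gs, ge in sched.apnea_gaps:
        i0, i1 = int(gs * fs), int(ge * fs)
        amp[i0:i1] *= cfg.apnea_gap_fraction
    x = amp * _bandpass_noise(n, fs, 100.0, 900.0, rng)

    for idx, ev in enumerate(sched.events):
        i0 = int(round(ev.start_s * fs))
        m = int(round(ev.duration_s * fs))
        m = min(m, n - i0)
        if m <= 8:
            continue
        env = signal.windows.hann(m)
        tt = np.arange(m) / fs
        if ev.event_class == "F":
            burst = _bandpass_noise(m, fs, 200.0, 1500.0, rng)
            x[i0:i0 + m] += cfg.f_burst_gain * cfg.breath_amplitude * env * burst
        elif ev.event_class == "S":
            # snore train: harmonic stack gated by the breathing cycle
            f0 = sched.snore_f0.get(idx, 100.0)
            tone = np.zeros(m)
            for h in range(1, 9):
                if h * f0 < 0.45 * fs:
                    tone += np.sin(2 * np.pi * h * f0 * tt + rng.uniform(0, 2 * np.pi)) / h
            tone /= max(tone.std(), 1e-12)
            gate = _breath_modulation(ev.start_s + tt, sched.breathing_rate_hz, cfg)
            env = signal.windows.tukey(m, alpha=min(1.0, 1.0 / ev.duration_s))
            x[i0:i0 + m] += cfg.snore_gain * cfg.breath_amplitude * env * gate * tone
        else:  # N
            kind = sched.noise_kind.get(idx, "burst")
            if kind == "click":
                burst = np.zeros(m)
                n_clicks = max(1, m // int(0.1 * fs + 1))
                pos = rng.integers(0, m, size=n_clicks)
                burst[pos] = rng.choice([-1.0, 1.0], size=n_clicks) * 8.0
            elif kind == "beep":
                fb = rng.uniform(400.0, 1600.0)
                burst = np.sqrt(2.0) * np.sin(2 * np.pi * fb * tt)
            else:
                burst = _bandpass_noise(m, fs, 50.0, 1900.0, rng)
            x[i0:i0 + m] += cfg.noise_gain * cfg.breath_amplitude * env * burst

    x += cfg.ambient_noise * rng.standard_normal(n)
    peak = np.abs(x).max()
    if peak > 1.0:
        x /= peak * 1.0001
    return AudioRecording(samples=x, fs=fs, subject_id=profile.subject_id), sched.events


def generate_subject_envelope(profile: SubjectProfile, duration_s: float,
                              dsr_s: float = 1.0,
                              rng: np.random.Generator | None = None,
                              cfg: GeneratorConfig | None = None,
                              ) -> tuple[np.ndarray, list]:
    """Fast mode: the log-variance envelope directly, same event schedule.

    The per-window variance is the amplitude-squared profile the audio
    renderer would produce (breathing modulation, apnea gaps, event bursts,
    ambient floor), integrated over each dsr_s window, plus Gaussian jitter
    emulating finite-window variance estimation.  Returns (values, events).
    """
    cfg = cfg or GeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    sched = _build_schedule(profile, duration_s, rng, cfg)
    fine_hz = 8.0
    n_fine = int(round(duration_s * fine_hz))
    t = np.arange(n_fine) / fine_hz

    amp = cfg.breath_amplitude * _breath_modulation(t, sched.breathing_rate_hz, cfg)
    for gs, ge in sched.apnea_gaps:
        amp[int(gs * fine_hz):int(ge * fine_hz)] *= cfg.apnea_gap_fraction
    var = amp ** 2
    for ev in sched.events:
        i0 = int(round(ev.start_s * fine_hz))
        m = max(int(round(ev.duration_s * fine_hz)), 1)
        m = min(m, n_fine - i0)
        if m < 1:
            continue
        gain = {"F": cfg.f_burst_gain, "S": cfg.snore_gain,
                "N": cfg.noise_gain}[ev.event_class]
        env = signal.windows.hann(m) if m > 2 else np.ones(m)
        var[i0:i0 + m] += (gain * cfg.breath_amplitude * env) ** 2
    var += cfg.ambient_noise ** 2

    per_win = int(round(dsr_s * fine_hz))
    n_out = n_fine // per_win
    v = var[: n_out * per_win].reshape(n_out, per_win).mean(axis=1)
    vals = np.log(v) + cfg.envelope_jitter_sd * rng.standard_normal(n_out)
    return vals, sched.events


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """A generated cohort: metadata plus per-subject audio or envelopes.

    When ``outdir`` is set the same content is also on disk (WAV/CSV).
    """

    metadata: pd.DataFrame
    audio: dict            # subject_id -> AudioRecording (audio mode)
    annotations: dict      # subject_id -> list[EventAnnotation]
    envelopes: dict        # subject_id -> {dsr_s: np.ndarray} (envelope mode)
    envelope_dsr_s: float | None = None
    outdir: Path | None = None


def _severity_counts(n: int, mix: dict) -> dict:
    """Largest-remainder allocation of n subjects to severity groups."""
    total = sum(mix.values())
    raw = {g: n * mix.get(g, 0.0) / total for g in SEVERITIES}
    counts = {g: int(np.floor(raw[g])) for g in SEVERITIES}
    rem = n - sum(counts.values())
    order = sorted(SEVERITIES, key=lambda g: raw[g] - counts[g], reverse=True)
    for g in order[:rem]:
        counts[g] += 1
    return counts


def make_profiles(n_subjects: int, severity_mix: dict | None, seed: int,
                  ) -> list[SubjectProfile]:
    """Deterministic subject profiles for a cohort."""
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    mix = severity_mix or DEFAULT_SEVERITY_MIX
    if abs(sum(mix.values()) - 1.0) > 1e-6:
        raise ValueError("severity_mix proportions must sum to 1")
    rng = np.random.default_rng(seed)
    counts = _severity_counts(n_subjects, mix)
    profiles = []
    i = 0
    for g in SEVERITIES:
        for _ in range(counts[g]):
            i += 1
            profiles.append(SubjectProfile(
                subject_id=f"S{i:03d}", severity=g,
                true_ahi=sample_ahi(g, rng),
                demographics=sample_demographics(g, rng),
                seed=int(rng.integers(0, 2 ** 31 - 1))))
    return profiles


def metadata_frame(profiles) -> pd.DataFrame:
    rows = []
    for p in profiles:
        d = p.demographics
        rows.append(dict(subject_id=p.subject_id, gender=d.gender,
                         age=round(d.age, 3), neck=round(d.neck, 3),
                         height=round(d.height, 3), weight=round(d.weight, 3),
                         bmi=round(d.bmi, 3), ess=d.ess,
                         true_ahi=round(p.true_ahi, 3), severity=p.severity,
                         label=assign_label(p.true_ahi)))
    return pd.DataFrame(rows)


def write_annotations_csv(events, path) -> None:
    pd.DataFrame([dict(event_class=e.event_class,
                       start_s=f"{e.start_s:.3f}",
                       duration_s=f"{e.duration_s:.3f}") for e in events],
                 columns=["event_class", "start_s", "duration_s"]).to_csv(
        path, index=False)


def read_annotations_csv(path) -> list:
    df = pd.read_csv(path)
    return [EventAnnotation(str(r.event_class), float(r.start_s),
                            float(r.duration_s)) for r in df.itertuples()]


def generate_cohort(n_subjects: int, duration_s: float, seed: int,
                    severity_mix: dict | None = None, fs: float = 4000.0,
                    mode: str = "audio", dsr_s: float = 1.0,
                    outdir=None, cfg: GeneratorConfig | None = None,
                    ) -> CohortBundle:
    """Generate a cohort; ``mode`` is "audio" or "envelope" (fast mode).

    Envelope mode emits log-variance envelopes at ``dsr_s`` for the analysis
    window directly, skipping audio synthesis.  With ``outdir`` set, WAVs /
    envelope CSVs, per-subject annotation CSVs and a metadata CSV are
    written there.
    """
    if mode not in ("audio", "envelope"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = cfg or GeneratorConfig()
    profiles = make_profiles(n_subjects, severity_mix, seed)
    meta = metadata_frame(profiles)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        (out / "annotations").mkdir(parents=True, exist_ok=True)
        sub = "audio" if mode == "audio" else "envelopes"
        (out / sub).mkdir(parents=True, exist_ok=True)

    audio, annotations, envelopes = {}, {}, {}
    for p in profiles:
        if mode == "audio":
            rec, events = generate_subject_audio(p, duration_s, fs, cfg=cfg)
            audio[p.subject_id] = rec
            if out is not None:
                wavfile.write(out / "audio" / f"{p.subject_id}.wav", int(fs),
                              np.round(rec.samples * 32767).astype(np.int16))
        else:
            vals, events = generate_subject_envelope(p, duration_s, dsr_s, cfg=cfg)
            envelopes[p.subject_id] = {dsr_s: vals}
            if out is not None:
                pd.DataFrame({"subject_id": p.subject_id, "dsr_s": dsr_s,
                              "value": vals}).to_csv(
                    out / "envelopes" / f"{p.subject_id}.csv", index=False,
                    float_format="%.6f")
        annotations[p.subject_id] = events
        if out is not None:
            write_annotations_csv(events, out / "annotations" / f"{p.subject_id}.csv")

    if out is not None:
        meta.to_csv(out / "metadata.csv", index=False, float_format="%.3f")
        manifest = dict(n_subjects=n_subjects, duration_s=duration_s,
                        seed=seed, fs=fs, mode=mode, dsr_s=dsr_s,
                        severity_mix=severity_mix or DEFAULT_SEVERITY_MIX,
                        generator_config={k: v for k, v in asdict(cfg).items()})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return CohortBundle(metadata=meta, audio=audio, annotations=annotations,
                        envelopes=envelopes,
                        envelope_dsr_s=dsr_s if mode == "envelope" else None,
                        outdir=out)
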