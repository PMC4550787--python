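"""Audio preprocessing for both analysis arms.

Severity arm: a fixed overnight analysis window (default: 240 min starting
30 min into the recording) is reduced to a log-variance envelope — the
natural log of the signal variance in consecutive non-overlapping windows
of 0.5, 1 or 2 s.  The log exaggerates breathing peaks while taming loud
spikes that would otherwise dominate any entropy measure.

Event arm: annotated F/S/N events are clipped to the first w seconds
(w in {0.5, 1, 2, 3}); events shorter than the window are excluded, so the
per-class survivor count is non-increasing in w.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import AudioRecording, EventAnnotation

DSR_GRID = (0.5, 1.0, 2.0)
EVENT_WINDOWS = (0.5, 1.0, 2.0, 3.0)

DEFAULT_START_OFFSET_S = 1800.0
DEFAULT_ANALYSIS_DURATION_S = 14400.0

#: Variance floor, in units of full-scale amplitude squared.
DEFAULT_EPS = 1e-12


class RecordingTooShortError(ValueError):
    """Raised when a recording cannot supply the requested analysis window."""


@dataclass
class EnvelopeSeries:
    """Log-variance envelope: one value per dsr_s-second window."""

    values: np.ndarray
    dsr_s: float
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("envelope values must be finite")

    @property
    def fs_effective(self) -> float:
        return 1.0 / self.dsr_s


@dataclass
class EventWindow:
    """First window_s seconds of an annotated event."""

    samples: np.ndarray
    window_s: float
    event_class: str
    subject_id: str = ""
    fs: float = 4000.0


@dataclass
class ExcludedEvent:
    """Marker for an event that did not survive clipping."""

    event_class: str
    reason: str
    subject_id: str = ""


def extract_analysis_window(audio: AudioRecording,
                            start_offset_s: float = DEFAULT_START_OFFSET_S,
                            duration_s: float = DEFAULT_ANALYSIS_DURATION_S,
                            ) -> np.ndarray:
    """Slice out the overnight analysis segment.

    Raises RecordingTooShortError when the recording cannot cover
    start_offset_s + duration_s (such recordings are excluded from the
    severity analysis rather than padded).
    """
    fs = audio.fs
    need = int(round((start_offset_s + duration_s) * fs))
    if audio.samples.shape[0] < need:
        raise RecordingTooShortError(
            f"recording {audio.subject_id or '?'} too short: "
            f"{audio.samples.shape[0] / fs:.0f} s < "
            f"{start_offset_s + duration_s:.0f} s required")
    i0 = int(round(start_offset_s * fs))
    return audio.samples[i0:i0 + int(round(duration_s * fs))]


def log_variance_envelope(segment, fs: float, dsr_s: float,
                          eps: float = DEFAULT_EPS,
                          subject_id: str = "") -> EnvelopeSeries:
    """ln of the per-window population variance, windows of dsr_s seconds.

    Windows are consecutive and non-overlapping; a trailing partial window
    is dropped.  Variances below eps are floored at eps so silence maps to
    ln(eps) instead of -inf.
    """
    x = np.asarray(segment, dtype=float)
    if eps <= 0:
        raise ValueError("eps must be > 0")
    win = dsr_s * fs
    n_win = int(round(win))
    if abs(win - n_win) > 1e-9 or n_win < 1:
        raise ValueError(f"dsr_s={dsr_s} is not a whole number of samples at fs={fs}")
    n_out = x.shape[0] // n_win
    if n_out < 1:
        raise ValueError("segment shorter than one variance window")
    blocks = x[: n_out * n_win].reshape(n_out, n_win)
    var = blocks.var(axis=1)  # population (1/n) variance
    vals = np.log(np.maximum(var, eps))
    return EnvelopeSeries(values=vals, dsr_s=dsr_s, subject_id=subject_id)


def clip_event_window(event: EventAnnotation, audio: AudioRecording,
                      window_s: float) -> EventWindow | ExcludedEvent:
    """First window_s seconds of an event, or an exclusion marker.

    Events strictly shorter than the window are excluded; an event whose
    duration equals the window exactly is included.  Events running past
    the end of the recording are excluded with a reason.
    """
    if event.duration_s < window_s:
        return ExcludedEvent(event.event_class, "shorter than window",
                             audio.subject_id)
    fs = audio.fs
    i0 = int(round(event.start_s * fs))
    n = int(round(window_s * fs))
    if i0 < 0 or i0 + n > audio.samples.shape[0]:
        return ExcludedEvent(event.event_class, "extends past recording end",
                             audio.subject_id)
    return EventWindow(samples=audio.samples[i0:i0 + n].copy(),
                       window_s=window_s, event_class=event.event_class,
                       subject_id=audio.subject_id, fs=fs)


def clip_events(events, audio: AudioRecording, window_s: float):
    """Clip all events; return (included windows, per-class survivor counts)."""
    included, counts = [], {}
    for ev in events:
        out = clip_event_window(ev, audio, window_s)
        if isinstance(out, EventWindow):
            included.append(out)
            counts[ev.event_class] = counts.get(ev.event_class, 0) + 1
    return included, counts


def write_envelope_csv(env: EnvelopeSeries, path) -> None:
    pd.DataFrame({"subject_id": env.subject_id, "dsr_s": env.dsr_s,
                  "value": env.values}).to_csv(path, index=False)


def read_envelope_csv(path) -> EnvelopeSeries:
    df = pd.read_csv(path)
    sid = str(df["subject_id"].iloc[0]) if len(df) else ""
    return EnvelopeSeries(values=df["value"].to_numpy(float),
                          dsr_s=float(df["dsr_s"].iloc[0]), subject_id=sid)
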