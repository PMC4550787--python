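"""LPC and MFCC features for F (choke) vs S/N (snore/noise) classification.

LPC: all-pole model of order 8 fitted by the autocorrelation method with
the Levinson–Durbin recursion.  Order 8 captures the first three formants,
enough to distinguish the broadband choke/first-breath events from the
harmonic structure of snores.

MFCC: each clipped event is a single frame — linear detrend, Hamming
window, magnitude spectrum, 24 triangular filters equally spaced on the
mel scale over 0..fs/2, log energies, DCT-II; coefficients 1..12 are kept
(the 0th is overall log energy and is discarded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.fft import dct, rfft

from .preprocess import EventWindow
from .synthetic import DEMOGRAPHIC_FEATURE_NAMES

LPC_ORDER = 8
MFCC_N_FILTERS = 24
MFCC_N_COEFFS = 12

#: Floor for log filterbank energies (relative, applied to power spectra).
MFCC_LOG_FLOOR = 1e-30


@dataclass
class LPCFeatures:
    """Predictor coefficients a1..a_order (x[n] ~ sum_k a_k x[n-k]) and gain."""

    coefficients: np.ndarray
    gain: float


@dataclass
class MFCCFeatures:
    coefficients: np.ndarray  # c1..c12


def levinson_durbin(autocorr, order: int):
    """Solve the Toeplitz normal equations; returns (a, residual_gain).

    ``a`` are predictor coefficients (positive convention); the prediction
    error filter is A(z) = 1 - sum_k a_k z^-k.
    """
    r = np.asarray(autocorr, dtype=float)
    if r[0] <= 0:
        raise ValueError("degenerate signal: zero autocorrelation at lag 0")
    a = np.zeros(order)
    err = r[0]
    for i in range(order):
        acc = r[i + 1] - a[:i] @ r[i:0:-1]
        k = acc / err
        a_new = a.copy()
        a_new[i] = k
        a_new[:i] = a[:i] - k * a[:i][::-1]
        a = a_new
        err *= (1.0 - k * k)
        if err <= 0:
            err = 0.0
            break
    return a, float(err)


def lpc_coefficients(window: EventWindow | np.ndarray,
                     order: int = LPC_ORDER) -> LPCFeatures:
    """Order-``order`` LPC of an event window (autocorrelation method).

    The window is mean-removed first.  The autocorrelation method guarantees
    a minimum-phase (stable) synthesis filter.
    """
    x = window.samples if isinstance(window, EventWindow) else np.asarray(window)
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n <= order:
        raise ValueError(f"window of {n} samples too short for order {order}")
    x = x - x.mean()
    if not np.any(x):
        raise ValueError("degenerate signal: all-zero window")
    full = np.correlate(x, x, mode="full")
    r = full[n - 1:n + order]
    a, err = levinson_durbin(r, order)
    return LPCFeatures(coefficients=a, gain=err / n)


def mel_from_hz(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def hz_from_mel(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, n_fft: int, fs: float) -> np.ndarray:
    """Triangular filters equally spaced on the mel scale over 0..fs/2.

    Adjacent filters overlap 50% (each filter spans its two neighbours'
    centers).  Shape: (n_filters, n_fft//2 + 1).
    """
    edges_mel = np.linspace(mel_from_hz(0.0), mel_from_hz(fs / 2.0),
                            n_filters + 2)
    edges_hz = hz_from_mel(edges_mel)
    freqs = np.arange(n_fft // 2 + 1) * fs / n_fft
    fb = np.zeros((n_filters, freqs.shape[0]))
    for i in range(n_filters):
        lo, c, hi = edges_hz[i], edges_hz[i + 1], edges_hz[i + 2]
        up = (freqs - lo) / max(c - lo, 1e-12)
        down = (hi - freqs) / max(hi - c, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mfcc_filter_centers_hz(n_filters: int = MFCC_N_FILTERS,
                           fs: float = 4000.0) -> np.ndarray:
    edges = np.linspace(mel_from_hz(0.0), mel_from_hz(fs / 2.0), n_filters + 2)
    return hz_from_mel(edges)[1:-1]


def mel_filter_energies(window: EventWindow | np.ndarray, fs: float = 4000.0,
                        n_filters: int = MFCC_N_FILTERS) -> np.ndarray:
    """Per-filter power of one detrended, Hamming-windowed event frame."""
    if isinstance(window, EventWindow):
        x, fs = window.samples, window.fs
    else:
        x = np.asarray(window, dtype=float)
    n = x.shape[0]
    if n < 64:
        raise ValueError("event window too short for spectral analysis")
    x = signal.detrend(x, type="linear")
    x = x * np.hamming(n)
    n_fft = 1 << (n - 1).bit_length()  # next power of two, zero-padded
    spec = np.abs(rfft(x, n=n_fft)) ** 2
    fb = mel_filterbank(n_filters, n_fft, fs)
    return fb @ spec


def mfcc(window: EventWindow | np.ndarray, fs: float = 4000.0,
         n_filters: int = MFCC_N_FILTERS,
         n_coeffs: int = MFCC_N_COEFFS) -> MFCCFeatures:
    """Single-frame MFCCs c1..c12 of an event window.

    Silent windows hit the log-energy floor rather than raising.
    """
    energies = mel_filter_energies(window, fs=fs, n_filters=n_filters)
    loge = np.log(np.maximum(energies, MFCC_LOG_FLOOR))
    c = dct(loge, type=2, norm="ortho")
    return MFCCFeatures(coefficients=c[1:n_coeffs + 1].copy())


def build_event_features(event_windows, feature_sets,
                         demographics_table: dict | None = None):
    """Feature matrix for clipped events; blocks concatenated in L|C|D order.

    feature_sets: subset of {"L", "C", "D"} (LPC, MFCC, demographics).
    demographics_table: subject_id -> Demographics (required when "D" set).
    Returns (X, y, subject_ids, column_names) with y = 1 for F events.
    """
    blocks = set(feature_sets)
    if not blocks or not blocks <= {"L", "C", "D"}:
        raise ValueError("feature_sets must be a non-empty subset of {'L','C','D'}")
    if "D" in blocks:
        missing = sorted({w.subject_id for w in event_windows}
                         - set(demographics_table or {}))
        if missing:
            raise ValueError(f"missing demographics for subjects: {missing}")
    cols = []
    if "L" in blocks:
        cols += [f"lpc_{i}" for i in range(1, LPC_ORDER + 1)]
    if "C" in blocks:
        cols += [f"mfcc_{i}" for i in range(1, MFCC_N_COEFFS + 1)]
    if "D" in blocks:
        cols += list(DEMOGRAPHIC_FEATURE_NAMES)
    rows, y, sids = [], [], []
    for w in event_windows:
        parts = []
        if "L" in blocks:
            parts.append(lpc_coefficients(w).coefficients)
        if "C" in blocks:
            parts.append(mfcc(w).coefficients)
        if "D" in blocks:
            parts.append(demographics_table[w.subject_id].as_vector())
        rows.append(np.concatenate(parts))
        y.append(1 if w.event_class == "F" else 0)
        sids.append(w.subject_id)
    X = np.vstack(rows) if rows else np.empty((0, len(cols)))
    return X, np.asarray(y, dtype=int), np.asarray(sids), cols
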