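"""Multiscale entropy (MSE) of a time series.

MSE characterises the complexity of a finite series by computing sample
entropy on successively coarse-grained versions of it.  Sample entropy
H_s(m, r, N) is the negative natural log of the conditional probability
that two subsequences that match for m points (Chebyshev distance within
r standard deviations, self-matches excluded) still match at point m+1.

For overnight audio envelopes, regular breathing produces low entropy at
short scales while the fragmented on/off structure of repeated apneas
raises entropy at longer scales, which is what makes the profile a
severity feature.

The match-counting kernel enumerates, for every diagonal offset d = j-i,
the runs of consecutive element-wise matches |x[t] - x[t+d]| <= r*sigma.
A run of length L starting at t yields template matches of every length
up to L, so the counts for all template lengths come out of one O(N^2)
pass.  This is exact: it reproduces the brute-force pairwise counts
integer for integer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

#: Scale factors used throughout the severity analysis.
DEFAULT_SCALES = (1, 2, 4, 8, 16, 32, 65, 130, 180)

M_GRID = tuple(range(1, 9))
R_GRID = (0.10, 0.15, 0.20, 0.25)


@dataclass(frozen=True)
class MSEParams:
    """Parameter bundle for one MSE profile.

    scales : strictly increasing positive integers (coarse-graining factors)
    m      : template length, 1..8
    r      : tolerance as a fraction of the scale-1 standard deviation
    """

    scales: tuple = DEFAULT_SCALES
    m: int = 2
    r: float = 0.15

    def __post_init__(self):
        sc = tuple(int(s) for s in self.scales)
        if len(sc) == 0 or sc[0] < 1 or any(b <= a for a, b in zip(sc, sc[1:])):
            raise ValueError("scales must be strictly increasing positive integers")
        if self.m < 1:
            raise ValueError("template length m must be >= 1")
        if not (0.0 < self.r < 1.0):
            raise ValueError("tolerance fraction r must lie in (0, 1)")
        object.__setattr__(self, "scales", sc)


@dataclass
class MSEProfile:
    """Sample entropies at each scale for a fixed (m, r), natural-log units.

    Undefined entries (zero match counts at length m or m+1, or a scale too
    short for the template) are NaN.
    """

    entropies: np.ndarray
    params: MSEParams
    sigma: float
    subject_id: str = ""

    n_scales: int = field(init=False)

    def __post_init__(self):
        self.entropies = np.asarray(self.entropies, dtype=float)
        if self.entropies.shape != (len(self.params.scales),):
            raise ValueError("entropies must align with params.scales")
        self.n_scales = len(self.params.scales)


def coarse_grain(x, tau: int) -> np.ndarray:
    """Average tau consecutive points in non-overlapping windows.

    Output length is floor(N / tau); a trailing partial window is dropped.
    tau = 1 returns the original series.
    """
    x = np.asarray(x, dtype=float)
    tau = int(tau)
    if tau < 1:
        raise ValueError("tau must be a positive integer")
    n = x.shape[0]
    if tau > n:
        raise ValueError(f"tau={tau} exceeds series length {n}")
    n_out = n // tau
    if tau == 1:
        return x.copy()
    return x[: n_out * tau].reshape(n_out, tau).mean(axis=1)


@njit(cache=False)
def _match_counts(x, thr, m_max):  # pragma: no cover - exercised via wrappers
    """Ordered-pair template match counts for all lengths 1..m_max+1.

    Returns (B, A) where, in the standard self-match-excluded convention,
    B[m-1] = #{(i, j), i != j, i,j in [0, N-m-1] : max_k |x[i+k]-x[j+k]| <= thr, k < m}
    A[m-1] = same with template length m+1 but indices still bounded by N-m-1.
    """
    N = x.shape[0]
    histB = np.zeros(m_max + 2, dtype=np.int64)
    histA = np.zeros(m_max + 2, dtype=np.int64)
    for d in range(1, N):
        L_next = 0
        for s in range(N - d - 1, -1, -1):
            if abs(x[s] - x[s + d]) <= thr:
                L = L_next + 1
            else:
                L = 0
            L_next = L
            if L > 0:
                # largest m with an m-template match at (s, s+d) and valid indices
                cap = N - 1 - (s + d)
                mB = min(L, m_max + 1, cap)
                if mB > 0:
                    histB[mB] += 1
                mA = min(L - 1, m_max, cap)
                if mA > 0:
                    histA[mA] += 1
    B = np.zeros(m_max + 1, dtype=np.int64)
    A = np.zeros(m_max, dtype=np.int64)
    accB = np.int64(0)
    for m in range(m_max + 1, 0, -1):
        accB += histB[m]
        B[m - 1] = 2 * accB
    accA = np.int64(0)
    for m in range(m_max, 0, -1):
        accA += histA[m]
        A[m - 1] = 2 * accA
    return B, A


def match_counts(x, thr: float, m_max: int):
    """Ordered-pair match counts B (lengths 1..m_max+1) and A (1..m_max).

    B[m-1] counts length-m template matches over indices i, j <= N-m-1
    (0-based, i != j); A[m-1] counts length-(m+1) matches over the same
    index range, so H_s(m) = -ln(A[m-1] / B[m-1]).
    """
    x = np.ascontiguousarray(x, dtype=float)
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    return _match_counts(x, float(thr), int(m_max))


def sample_entropy(x, m: int, r: float, sigma: float) -> float:
    """Sample entropy H_s = -ln(A/B) with tolerance r*sigma, Chebyshev distance.

    Returns NaN (the "undefined" sentinel) when no matches exist at length
    m or m+1; raises if sigma is not strictly positive or the series is too
    short to form a single (m+1)-template pair.
    """
    x = np.asarray(x, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    m = int(m)
    if x.shape[0] < m + 2:
        raise ValueError(f"series length {x.shape[0]} < m + 2 = {m + 2}")
    B, A = match_counts(x, r * sigma, m)
    b, a = B[m - 1], A[m - 1]
    if b == 0 or a == 0:
        logger.debug("sample_entropy undefined: B=%d A=%d (m=%d)", b, a, m)
        return float("nan")
    return float(-np.log(a / b))


def mse_profile(envelope, params: MSEParams, sigma: float | None = None,
                subject_id: str = "") -> MSEProfile:
    """MSE profile of a series over ``params.scales``.

    The tolerance anchor sigma is the standard deviation of the *original*
    (scale-1) series and is reused at every scale; scales whose
    coarse-grained series is too short yield NaN and a log entry.
    """
    x = np.asarray(envelope, dtype=float)
    if sigma is None:
        sigma = float(np.std(x))
    if sigma <= 0:
        raise ValueError("sigma of the scale-1 series must be > 0")
    ents = np.full(len(params.scales), np.nan)
    for k, tau in enumerate(params.scales):
        if tau > x.shape[0]:
            logger.warning("scale %d exceeds series length %d; undefined", tau, len(x))
            continue
        y = coarse_grain(x, tau)
        if y.shape[0] < params.m + 2:
            logger.warning("scale %d leaves %d points (< m+2); undefined", tau, len(y))
            continue
        ents[k] = sample_entropy(y, params.m, params.r, sigma)
    return MSEProfile(entropies=ents, params=params, sigma=float(sigma),
                      subject_id=subject_id)


def entropy_table(envelope, m_values=M_GRID, r_values=R_GRID,
                  scales=DEFAULT_SCALES) -> np.ndarray:
    """Entropies for every (m, r, scale) combination in one pass per (r, scale).

    Returns an array of shape (len(m_values), len(r_values), len(scales));
    undefined entries are NaN.  The tolerance anchor is the scale-1 sigma.
    Used by the severity pipeline, where the grid search needs the full
    m x r grid for every subject.
    """
    x = np.asarray(envelope, dtype=float)
    sigma = float(np.std(x))
    if sigma <= 0:
        raise ValueError("sigma of the scale-1 series must be > 0")
    m_values = [int(m) for m in m_values]
    m_max = max(m_values)
    out = np.full((len(m_values), len(r_values), len(scales)), np.nan)
    for si, tau in enumerate(scales):
        if tau > x.shape[0]:
            continue
        y = coarse_grain(x, tau)
        if y.shape[0] < min(m_values) + 2:
            continue
        for ri, r in enumerate(r_values):
            B, A = match_counts(y, r * sigma, m_max)
            for mi, m in enumerate(m_values):
                if y.shape[0] < m + 2:
                    continue
                b, a = B[m - 1], A[m - 1]
                if b > 0 and a > 0:
                    out[mi, ri, si] = -np.log(a / b)
    return out
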