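"""R-peak detection, beat segmentation and per-beat normalization.

R peaks are found with the Pan-Tompkins chain (band-pass, derivative,
squaring, moving-window integration, adaptive thresholds with refractory
and searchback) on a single reference channel; the resulting fiducials are
shared across leads so per-beat features stay time-aligned. Each beat —
the span between two neighboring R peaks — is resampled to 400 samples via
cubic splines (recording the time factor alpha = N/400) and min-max scaled
to [0, 1] (recording the amplitude range beta per lead).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .signal_io import MultiLeadRecord

__all__ = [
    "BeatSegment",
    "NormalizedBeat",
    "Heartbeat",
    "DegenerateBeatError",
    "detect_r_peaks",
    "segment_beats",
    "period_normalize",
    "minmax_scale",
    "normalize_heartbeat",
]

log = logging.getLogger(__name__)

TARGET_LEN = 400
#: physiological RR bounds, in seconds (100 and 1500 samples at 500 Hz)
MIN_RR_S = 0.2
MAX_RR_S = 3.0


class DegenerateBeatError(ValueError):
    """Raised when a beat cannot be normalized (e.g. constant amplitude)."""


@dataclass
class BeatSegment:
    """One lead's samples between two neighboring R peaks ([start, end))."""

    lead: str
    samples: np.ndarray
    start: int

    @property
    def n(self) -> int:
        return len(self.samples)


@dataclass
class NormalizedBeat:
    """400 samples scaled to [0, 1] with its scaling factors.

    ``alpha`` is the original length over 400; ``beta`` the amplitude range
    removed by min-max scaling (in signal units).
    """

    values: np.ndarray
    alpha: float
    beta: float
    lead: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != TARGET_LEN:
            raise ValueError(f"normalized beat must have {TARGET_LEN} samples")


@dataclass
class Heartbeat:
    """All leads of one beat sharing the same [start, end) fiducials."""

    start: int
    end: int
    segments: dict[str, BeatSegment]

    @property
    def n(self) -> int:
        return self.end - self.start


def _pan_tompkins_integrated(x: np.ndarray, fs: float) -> np.ndarray:
    """Band-pass -> derivative -> square -> moving-window integration."""
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    # classic five-point derivative
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(filtered, kernel[::-1], mode="same")
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    return np.convolve(squared, np.ones(win) / win, mode="same")


def detect_r_peaks(
    signal: np.ndarray,
    fs: float,
    refractory_s: float = 0.2,
) -> np.ndarray:
    """Detect R-peak sample indices with adaptive Pan-Tompkins thresholds.

    Returns a strictly increasing index array (possibly empty) with minimum
    separation ``refractory_s``.
    """
    x = np.asarray(signal, dtype=float)
    if fs < 100:
        raise ValueError("sampling rate must be at least 100 Hz")
    if len(x) < 2 * fs:
        raise ValueError("signal must be at least 2 s long")
    if np.ptp(x) == 0:
        return np.array([], dtype=int)

    integ = _pan_tompkins_integrated(x, fs)
    distance = max(1, int(round(refractory_s * fs)))
    candidates, _ = sps.find_peaks(integ, distance=distance)
    if len(candidates) == 0:
        return np.array([], dtype=int)

    head = integ[: int(2 * fs)]
    spki = 0.5 * head.max()
    npki = 0.5 * float(np.mean(head))
    threshold = npki + 0.25 * (spki - npki)

    accepted: list[int] = []
    rr_history: list[float] = []
    deferred: list[int] = []  # sub-threshold candidates for searchback
    for p in candidates:
        if integ[p] > threshold:
            if accepted and rr_history:
                avg_rr = float(np.mean(rr_history[-8:]))
                gap = p - accepted[-1]
                if gap > 1.66 * avg_rr and deferred:
                    # searchback at half threshold inside the gap
                    back = [q for q in deferred if accepted[-1] < q < p and integ[q] > 0.5 * threshold]
                    if back:
                        q = max(back, key=lambda idx: integ[idx])
                        rr_history.append(q - accepted[-1])
                        accepted.append(q)
                        spki = 0.25 * integ[q] + 0.75 * spki
            if accepted:
                rr_history.append(p - accepted[-1])
            accepted.append(p)
            spki = 0.125 * integ[p] + 0.875 * spki
            deferred = []
        else:
            npki = 0.125 * integ[p] + 0.875 * npki
            deferred.append(p)
        threshold = npki + 0.25 * (spki - npki)

    # refine each detection to the local maximum of the raw signal
    half = int(round(0.10 * fs))
    refined = []
    for p in accepted:
        lo = max(0, p - half)
        hi = min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = sorted(set(refined))

    # enforce the refractory period after refinement (keep the taller peak)
    out: list[int] = []
    for p in refined:
        if out and p - out[-1] < distance:
            if x[p] > x[out[-1]]:
                out[-1] = p
        else:
            out.append(p)
    return np.array(out, dtype=int)


def segment_beats(
    record: MultiLeadRecord,
    rpeaks: np.ndarray,
    min_rr_s: float = MIN_RR_S,
    max_rr_s: float = MAX_RR_S,
    edge_guard_s: float = 0.0,
) -> tuple[list[Heartbeat], list[tuple[int, int, str]]]:
    """Split all leads into beats between neighboring R peaks.

    Fiducials are shared across leads. Beats violating the RR bounds or
    overlapping the edge guard (``edge_guard_s`` seconds at each end,
    excluded because of filter transients) are dropped; the second return
    value logs ``(start, end, reason)`` per rejection.
    """
    rpeaks = np.asarray(rpeaks, dtype=int)
    if len(rpeaks) < 2:
        raise ValueError("need at least 2 R peaks to segment beats")
    fs = record.sampling_rate
    lo_bound = int(round(min_rr_s * fs))
    hi_bound = int(round(max_rr_s * fs))
    guard = int(round(edge_guard_s * fs))
    beats: list[Heartbeat] = []
    rejected: list[tuple[int, int, str]] = []
    for start, end in zip(rpeaks[:-1], rpeaks[1:]):
        n = end - start
        if n < lo_bound:
            rejected.append((start, end, f"RR {n} samples below {lo_bound}"))
            continue
        if n > hi_bound:
            rejected.append((start, end, f"RR {n} samples above {hi_bound}"))
            continue
        if start < guard or end > record.n_samples - guard:
            rejected.append((start, end, "inside edge guard"))
            continue
        segments = {
            name: BeatSegment(name, record.leads[name][start:end], int(start))
            for name in record.leads
        }
        beats.append(Heartbeat(int(start), int(end), segments))
    if rejected:
        log.info("segment_beats: dropped %d of %d beats", len(rejected), len(rpeaks) - 1)
    return beats, rejected


def period_normalize(
    samples: np.ndarray, target_len: int = TARGET_LEN
) -> tuple[np.ndarray, float]:
    """Cubic-spline resample a beat to ``target_len`` evenly spaced points.

    Sample ``i`` of the input is identified with normalized time
    ``(i + 1) / N``; the output grid is ``j / target_len, j = 1..target_len``,
    so an input already of the target length is returned unchanged. Returns
    ``(resampled, alpha)`` with ``alpha = N / target_len``.
    """
    y = np.asarray(samples, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError(f"beat of {n} samples is too short to spline-interpolate")
    alpha = n / target_len
    if n == target_len:
        return y.copy(), alpha
    spline = CubicSpline(np.arange(n), y)
    grid = (np.arange(1, target_len + 1) / target_len) * n - 1.0
    return spline(grid), alpha


def minmax_scale(samples: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale to [0, 1]; returns the scaled values and the range beta.

    A constant sequence has no amplitude information and is rejected.
    """
    y = np.asarray(samples, dtype=float)
    lo, hi = float(np.min(y)), float(np.max(y))
    beta = hi - lo
    if beta == 0:
        raise DegenerateBeatError("constant beat cannot be min-max scaled")
    return (y - lo) / beta, beta


def normalize_heartbeat(
    beat: Heartbeat, leads: list[str] | None = None, target_len: int = TARGET_LEN
) -> dict[str, NormalizedBeat]:
    """Normalize every requested lead of one beat (shared alpha, per-lead beta)."""
    names = leads if leads is not None else list(beat.segments)
    out: dict[str, NormalizedBeat] = {}
    for name in names:
        seg = beat.segments[name]
        resampled, alpha = period_normalize(seg.samples, target_len)
        scaled, beta = minmax_scale(resampled)
        out[name] = NormalizedBeat(scaled, alpha, beta, lead=name)
    return out
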