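"""Physiological gating: breath detection, R-wave detection, ECG-R gating.

Frames acquired during a breath (between inhalation onset and the onset of
the post-exhalation pause) carry bulk motion and are discarded.  The
survivors are re-ordered by their delay from the nearest preceding ECG
R wave, which folds several minutes of free-running acquisition into a
single reconstructed cardiac cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "PhysioTrace",
    "BreathEvents",
    "GatedCycle",
    "detect_breaths",
    "detect_r_waves",
    "respiratory_gate",
    "reorder_by_cardiac_delay",
    "reconstruct_gated_ecg",
]


@dataclass
class PhysioTrace:
    """Uniformly sampled physiological signal (ECG or respiration)."""

    samples: np.ndarray
    sampling_rate_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.samples.size < 2:
            raise ValueError("trace must hold at least 2 samples")

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.samples.size) / self.sampling_rate_hz

    @property
    def duration_s(self) -> float:
        return (self.samples.size - 1) / self.sampling_rate_hz


@dataclass
class BreathEvents:
    """Per-breath event times: inhalation onset < peak < exhalation-pause onset."""

    onsets_s: np.ndarray
    peaks_s: np.ndarray
    pause_onsets_s: np.ndarray

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.peaks_s = np.asarray(self.peaks_s, dtype=float)
        self.pause_onsets_s = np.asarray(self.pause_onsets_s, dtype=float)
        n = self.onsets_s.size
        if self.peaks_s.size != n or self.pause_onsets_s.size != n:
            raise ValueError("event arrays must have equal length")
        if n:
            if not (np.all(self.onsets_s < self.peaks_s) and np.all(self.peaks_s < self.pause_onsets_s)):
                raise ValueError("each breath requires onset < peak < pause onset")
            if np.any(self.onsets_s[1:] < self.pause_onsets_s[:-1]):
                raise ValueError("breaths must be non-overlapping and time-ordered")

    def __len__(self) -> int:
        return self.onsets_s.size


@dataclass
class GatedCycle:
    """Result of ECG-R gating: kept frames ordered by cardiac delay."""

    kept_indices: np.ndarray
    cardiac_delays_s: np.ndarray
    gated_ecg: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.kept_indices = np.asarray(self.kept_indices, dtype=int)
        self.cardiac_delays_s = np.asarray(self.cardiac_delays_s, dtype=float)
        if self.kept_indices.shape != self.cardiac_delays_s.shape:
            raise ValueError("one delay per kept frame required")
        if self.cardiac_delays_s.size > 1 and np.any(np.diff(self.cardiac_delays_s) < 0):
            raise ValueError("cardiac delays must be non-decreasing in output order")

    @property
    def n_frames(self) -> int:
        return self.kept_indices.size


def detect_breaths(
    resp: PhysioTrace,
    smoothing_window_s: float = 0.1,
    prominence_fraction: float = 0.3,
    *,
    onset_fraction: float = 0.05,
    slope_fraction: float = 0.05,
) -> BreathEvents:
    """Detect breaths on a respiration trace.

    The trace is smoothed with a centred moving average, inhalation peaks
    are picked with a prominence of ``prominence_fraction`` times the trace
    range, and for each peak:

    * the inhalation onset is the last pre-peak sample at or below the local
      baseline plus ``onset_fraction`` of the peak height above it;
    * the exhalation-pause onset is the first sample after the point of
      steepest descent where the downslope magnitude has decayed below
      ``slope_fraction`` of that steepest descent.

    A flat trace yields an empty event list.  Breaths whose events cannot
    be resolved inside the trace are dropped.
    """
    x = resp.samples
    rng = float(x.max() - x.min())
    if rng == 0.0:
        return BreathEvents(np.empty(0), np.empty(0), np.empty(0))
    win = max(1, int(round(smoothing_window_s * resp.sampling_rate_hz)))
    if win >= x.size:
        raise ValueError("trace shorter than the smoothing window")
    sm = uniform_filter1d(x, size=win, mode="nearest")
    peaks, _ = find_peaks(sm, prominence=prominence_fraction * rng)
    slope = np.gradient(sm)

    onsets, kept_peaks, pauses = [], [], []
    prev_bound = 0
    for j, p in enumerate(peaks):
        # local baseline between the previous breath and this peak
        seg = sm[prev_bound:p]
        if seg.size == 0:
            continue
        baseline = seg.min()
        thr = baseline + onset_fraction * (sm[p] - baseline)
        below = np.nonzero(seg <= thr)[0]
        if below.size == 0:
            continue
        onset = prev_bound + below[-1]

        nxt = peaks[j + 1] if j + 1 < len(peaks) else sm.size
        fall = slope[p:nxt]
        if fall.size < 2:
            continue
        steepest = int(np.argmin(fall))  # most negative slope
        peak_fall = abs(fall[steepest])
        if peak_fall == 0:
            continue
        calm = np.nonzero(np.abs(fall[steepest:]) <= slope_fraction * peak_fall)[0]
        if calm.size == 0:
            continue
        pause = p + steepest + calm[0]

        if onsets and onset / resp.sampling_rate_hz + resp.t0_s <= pauses[-1]:
            continue  # would overlap the previous breath
        onsets.append(resp.t0_s + onset / resp.sampling_rate_hz)
        kept_peaks.append(resp.t0_s + p / resp.sampling_rate_hz)
        pauses.append(resp.t0_s + pause / resp.sampling_rate_hz)
        prev_bound = pause
    return BreathEvents(np.array(onsets), np.array(kept_peaks), np.array(pauses))


def detect_r_waves(
    ecg: PhysioTrace,
    min_rr_s: float = 0.12,
    threshold_fraction: float = 0.6,
) -> np.ndarray:
    """Detect R-wave times by thresholded peak picking with a refractory period.

    Candidate peaks above ``threshold_fraction * max(ecg)`` are accepted
    greedily in order of decreasing amplitude; a candidate closer than
    ``min_rr_s`` to an already accepted R wave is suppressed.  Returned
    times are strictly increasing with consecutive gaps >= ``min_rr_s``.
    """
    if min_rr_s <= 0:
        raise ValueError("min_rr_s must be > 0")
    x = ecg.samples
    thr = threshold_fraction * x.max()
    cand, _ = find_peaks(x, height=thr)
    # endpoints can carry the maximum without being a local interior peak
    for edge in (0, x.size - 1):
        inner = 1 if edge == 0 else x.size - 2
        if x[edge] >= thr and x[edge] > x[inner]:
            cand = np.sort(np.append(cand, edge))
    if cand.size == 0:
        return np.empty(0)
    order = np.argsort(x[cand], kind="stable")[::-1]
    kept: list[int] = []
    min_gap = min_rr_s * ecg.sampling_rate_hz
    for idx in cand[order]:
        if all(abs(idx - k) >= min_gap for k in kept):
            kept.append(int(idx))
    kept.sort()
    return ecg.t0_s + np.array(kept, dtype=float) / ecg.sampling_rate_hz


def respiratory_gate(timestamps: np.ndarray, events: BreathEvents) -> np.ndarray:
    """Indices of frames lying in no closed gate [onset, pause onset].

    With no breath events this is the identity on frame indices.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if timestamps.size > 1 and not np.all(np.diff(timestamps) > 0):
        raise ValueError("timestamps must be strictly increasing")
    keep = np.ones(timestamps.size, dtype=bool)
    for a, b in zip(events.onsets_s, events.pause_onsets_s):
        keep &= ~((timestamps >= a) & (timestamps <= b))
    return np.nonzero(keep)[0]


def reorder_by_cardiac_delay(
    timestamps: np.ndarray,
    kept_frame_indices: np.ndarray,
    r_times: np.ndarray,
) -> GatedCycle:
    """Sort kept frames by their delay from the latest preceding R wave.

    Delay = timestamp - (latest R wave <= timestamp).  Sorting is stable,
    so frames with identical delay keep acquisition order.  Frames earlier
    than the first R wave have no defined delay and are dropped with a
    logged warning.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    kept = np.asarray(kept_frame_indices, dtype=int)
    r_times = np.sort(np.asarray(r_times, dtype=float))
    if r_times.size == 0:
        raise ValueError("at least one R wave is required")
    ts = timestamps[kept]
    pos = np.searchsorted(r_times, ts, side="right") - 1
    valid = pos >= 0
    n_dropped = int(np.count_nonzero(~valid))
    if n_dropped:
        logger.warning("%d frame(s) precede the first R wave and were dropped", n_dropped)
    kept, ts, pos = kept[valid], ts[valid], pos[valid]
    if kept.size == 0:
        raise ValueError("no kept frame follows the first R wave")
    delays = ts - r_times[pos]
    order = np.argsort(delays, kind="stable")
    return GatedCycle(kept_indices=kept[order], cardiac_delays_s=delays[order])


def reconstruct_gated_ecg(
    ecg: PhysioTrace, cycle: GatedCycle, timestamps: np.ndarray
) -> np.ndarray:
    """ECG value at each kept frame, sampled at the nearest ECG sample time.

    A timestamp exactly midway between two ECG samples takes the earlier
    sample.  Timestamps outside the ECG span raise.  The values are also
    stored on ``cycle.gated_ecg``.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    ts = timestamps[cycle.kept_indices]
    t_end = ecg.t0_s + (ecg.samples.size - 1) / ecg.sampling_rate_hz
    if np.any(ts < ecg.t0_s) or np.any(ts > t_end):
        raise ValueError("frame timestamp outside the ECG trace span")
    s = (ts - ecg.t0_s) * ecg.sampling_rate_hz
    lo = np.floor(s).astype(int)
    frac = s - lo
    idx = np.where(frac > 0.5, lo + 1, lo)  # tie (0.5) -> earlier sample
    idx = np.clip(idx, 0, ecg.samples.size - 1)
    values = ecg.samples[idx]
    cycle.gated_ecg = values
    return values
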