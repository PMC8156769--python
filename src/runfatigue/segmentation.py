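"""Gait segmentation of running sessions.

Stages, all driven by the pelvis forward velocity and the right knee
angle:

1. run bounds — zero-crossings of the pelvis sagittal velocity around
   its sustained-positive stretches;
2. stride events — downward peaks (local minima) of the pelvis velocity,
   gated by prominence and a minimum separation;
3. initial contacts — per stride, the right knee extension minimum
   nearest the stride event gives the right initial contact, and the
   analogous minimum half a stride later gives the left one;
4. cycle cutting — per side, the interval between consecutive
   same-side initial contacts, with every signal linearly resampled to
   150 points.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import find_peaks

from .errors import NoRunDetected, SegmentationError, ValidationError
from .types import (CYCLE_POINTS, JOINTS, LOCATION_CODES, GaitCycle,
                    SessionRecording)
from .features import accel_magnitude

logger = logging.getLogger(__name__)

#: Peak-detection gates (scale-free defaults).
PROMINENCE_IQR_FACTOR = 0.2
MIN_SEPARATION_PERIOD_FACTOR = 0.5
#: Knee-landmark search half-window as a fraction of the stride period.
IC_SEARCH_FRACTION = 0.3
#: Cycles shorter than this many samples are dropped.
MIN_CYCLE_SAMPLES = 10


# ---------------------------------------------------------------------------
# run bounds
# ---------------------------------------------------------------------------

def detect_runs(pelvis_velocity, fs: float, min_duration_s: float = 2.0
                ) -> list[tuple[int, int]]:
    """All sustained running bouts as half-open sample intervals.

    A bout is a stretch where the 1 s moving average of the velocity
    exceeds half of its 95th percentile; its limits are refined to the
    enclosing zero-crossings of the raw velocity.
    """
    v = np.asarray(pelvis_velocity, dtype=float)
    if v.ndim != 1 or v.shape[0] < 2 * fs:
        raise ValidationError("pelvis_velocity: need at least 2 s of signal")
    win = max(1, int(round(fs)))
    kernel = np.ones(win) / win
    ma = np.convolve(v, kernel, mode="same")
    level = np.percentile(ma, 95)
    if level <= 0:
        raise NoRunDetected("no sustained positive pelvis velocity")
    sustained = ma > 0.5 * level
    if not sustained.any():
        raise NoRunDetected("no sustained positive pelvis velocity")

    # contiguous sustained regions
    edges = np.flatnonzero(np.diff(sustained.astype(int)))
    starts = [0] if sustained[0] else []
    stops: list[int] = []
    for e in edges:
        if sustained[e + 1]:
            starts.append(e + 1)
        else:
            stops.append(e + 1)
    if sustained[-1]:
        stops.append(v.shape[0])

    # the centered moving average smears region edges by up to half a
    # window, so crossings are searched with a window-sized margin
    ups = np.flatnonzero((v[:-1] <= 0) & (v[1:] > 0)) + 1
    downs = np.flatnonzero((v[:-1] > 0) & (v[1:] <= 0)) + 1
    bouts: list[tuple[int, int]] = []
    for a, b in zip(starts, stops):
        prior = ups[ups <= a + win]
        start = int(prior[-1]) if prior.size else int(a)
        after = downs[downs >= b - win]
        end = int(after[0]) if after.size else int(v.shape[0])
        if end > start and (end - start) / fs >= min_duration_s:
            if bouts and start < bouts[-1][1]:
                continue
            bouts.append((start, end))
    if not bouts:
        raise NoRunDetected("no bout longer than the minimum duration")
    return bouts


def detect_run_bounds(pelvis_velocity, fs: float) -> tuple[int, int]:
    """Bounds of the first running bout (see :func:`detect_runs`)."""
    return detect_runs(pelvis_velocity, fs)[0]


# ---------------------------------------------------------------------------
# stride events
# ---------------------------------------------------------------------------

def detect_strides(pelvis_velocity, fs: float,
                   bounds: tuple[int, int]) -> np.ndarray:
    """Downward pelvis-velocity peaks (one per stride) within ``bounds``.

    Two passes of peak detection on the negated velocity: the first,
    gated only by prominence (0.2 x signal IQR), estimates the stride
    period; the second adds a minimum separation of half that period.
    """
    start, end = bounds
    v = np.asarray(pelvis_velocity, dtype=float)[start:end]
    if v.shape[0] < 4:
        raise SegmentationError("bounds too short for stride detection")
    q75, q25 = np.percentile(v, [75, 25])
    prominence = max(PROMINENCE_IQR_FACTOR * (q75 - q25), 1e-12)
    first, _ = find_peaks(-v, prominence=prominence)
    if first.shape[0] < 2:
        raise SegmentationError("fewer than 2 velocity minima found")
    period = float(np.median(np.diff(first)))
    distance = max(1.0, MIN_SEPARATION_PERIOD_FACTOR * period)
    peaks, _ = find_peaks(-v, prominence=prominence, distance=distance)
    if peaks.shape[0] < 2:
        raise SegmentationError("fewer than 2 velocity minima found")
    return peaks + start


# ---------------------------------------------------------------------------
# initial contacts
# ---------------------------------------------------------------------------

def _nearest_minimum(signal: np.ndarray, lo: int, hi: int,
                     target: int) -> int | None:
    """Index of the local minimum of ``signal[lo:hi]`` nearest ``target``."""
    lo = max(lo, 0)
    hi = min(hi, signal.shape[0])
    if hi - lo < 3:
        return None
    window = signal[lo:hi]
    minima, _ = find_peaks(-window, prominence=0.5)
    if minima.size == 0:
        return None
    minima = minima + lo
    return int(minima[np.argmin(np.abs(minima - target))])


def detect_initial_contacts(right_knee_angle, stride_peaks,
                            fs: float) -> list[tuple[int, str]]:
    """Left and right initial contacts from the right knee angle.

    The right initial contact of each stride is the knee extension
    minimum within +-30% of the stride period around the stride event;
    the left initial contact is the analogous minimum half a stride
    later.  Strides without both landmarks are skipped (flagged
    unusable), so the returned sides alternate strictly.
    """
    knee = np.asarray(right_knee_angle, dtype=float)
    peaks = np.asarray(stride_peaks, dtype=int)
    if peaks.size == 0:
        raise ValidationError("stride_peaks: must be non-empty")
    if peaks.size < 2:
        raise SegmentationError("need at least 2 stride events")
    period = float(np.median(np.diff(peaks)))
    half = int(round(IC_SEARCH_FRACTION * period))
    contacts: list[tuple[int, str]] = []
    n_unusable = 0
    for p in peaks:
        r_ic = _nearest_minimum(knee, p - half, p + half + 1, p)
        l_target = p + int(round(0.5 * period))
        l_ic = _nearest_minimum(knee, l_target - half, l_target + half + 1,
                                l_target)
        if r_ic is None or l_ic is None or l_ic <= r_ic:
            n_unusable += 1
            continue
        if contacts and r_ic <= contacts[-1][0]:
            n_unusable += 1
            continue
        contacts.append((r_ic, "right"))
        contacts.append((l_ic, "left"))
    if n_unusable:
        logger.info("flagged %d of %d strides unusable", n_unusable, peaks.size)
    return contacts


# ---------------------------------------------------------------------------
# cycle cutting and time normalization
# ---------------------------------------------------------------------------

def derived_signals(recording: SessionRecording) -> dict[str, np.ndarray]:
    """Per-sample signals entering the gait cycles.

    8 acceleration magnitudes, 8 pitch angular velocities (medio-lateral
    gyroscope component) and 6 sagittal joint angles.
    """
    out: dict[str, np.ndarray] = {}
    for code in LOCATION_CODES:
        if code not in recording.segment_streams:
            continue
        acc = recording.segment_streams[code]["accel"]
        out[f"{code}_accel_mag"] = accel_magnitude(acc[:, 0], acc[:, 1], acc[:, 2])
        out[f"{code}_angvel_pitch"] = recording.segment_streams[code]["angvel"][:, 1]
    for joint in JOINTS:
        if joint in recording.joint_streams:
            out[f"{joint}_angle"] = recording.joint_streams[joint]
    return out


def resample_curve(curve: np.ndarray, n_points: int = CYCLE_POINTS) -> np.ndarray:
    """Linear time-normalization of one cycle's samples to ``n_points``."""
    curve = np.asarray(curve, dtype=float)
    if curve.shape[0] < 2:
        raise ValidationError("resample_curve: need at least 2 samples")
    src = np.arange(curve.shape[0])
    dst = np.linspace(0.0, curve.shape[0] - 1.0, n_points)
    return np.interp(dst, src, curve)


def segment_and_normalize(recording: SessionRecording,
                          initial_contacts: list[tuple[int, str]],
                          signals: dict[str, np.ndarray] | None = None
                          ) -> list[GaitCycle]:
    """Cut signals into per-side gait cycles normalized to 150 points.

    Cycle *k* of a side spans the half-open interval between that side's
    initial contacts *k* and *k+1*.  Cycles shorter than
    ``MIN_CYCLE_SAMPLES`` samples or longer than 1.8x the side's median
    cycle are dropped (with a log entry); the latter arise when an
    unusable stride was skipped during contact detection.
    """
    if signals is None:
        signals = derived_signals(recording)
    fs = recording.sampling_rate
    speed = recording.nominal_speed_mps
    cycles: list[GaitCycle] = []
    for side in ("right", "left"):
        ics = np.array([i for i, s in initial_contacts if s == side], dtype=int)
        if ics.size < 2:
            continue
        lengths = np.diff(ics)
        max_len = 1.8 * float(np.median(lengths))
        n_dropped = 0
        for s, e in zip(ics[:-1], ics[1:]):
            if (e - s) < MIN_CYCLE_SAMPLES or (e - s) > max_len:
                n_dropped += 1
                continue
            stride_time = (e - s) / fs
            cycles.append(GaitCycle(
                side=side,
                start_index=int(s),
                end_index=int(e),
                stride_time=stride_time,
                stride_distance=speed * stride_time,
                curves={name: resample_curve(sig[s:e])
                        for name, sig in signals.items()},
            ))
        if n_dropped:
            logger.info("dropped %d %s cycles (too short or spanning a gap)",
                        n_dropped, side)
    return cycles


def pair_cycles(cycles: list[GaitCycle]
                ) -> list[tuple[GaitCycle, GaitCycle]]:
    """Match each right cycle with the left cycle starting inside it."""
    rights = [c for c in cycles if c.side == "right"]
    lefts = [c for c in cycles if c.side == "left"]
    left_starts = np.array([c.start_index for c in lefts], dtype=int)
    pairs: list[tuple[GaitCycle, GaitCycle]] = []
    for r in rights:
        j = np.searchsorted(left_starts, r.start_index, side="right")
        if j < len(lefts) and lefts[j].start_index < r.end_index:
            pairs.append((r, lefts[j]))
    return pairs
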