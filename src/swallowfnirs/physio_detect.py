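"""Swallow-onset detection from laryngeal accelerometry gated by apnea.

The respiratory trace identifies swallow apneas (pauses in breathing);
within each apnea the rectified, Bartlett-smoothed accelerometer
envelope's derivative is searched for its first sustained positive
zero-crossing — the moment hyolaryngeal movement begins.  Detected
onsets are then labelled with head position, block and within-segment
ordinal from the session schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import oaconvolve
from scipy.signal.windows import triang

from .synthgen import (ACCEL_RATE, RESP_RATE, ConfigurationError, Schedule,
                       SessionRecording)

__all__ = [
    "ApneaInterval",
    "SwallowEvent",
    "IntegrityError",
    "detect_apnea",
    "envelope",
    "derivative",
    "detect_onsets",
    "assign_conditions",
    "detect_swallows",
    "evaluate_detection",
]


class IntegrityError(RuntimeError):
    """Data inconsistent with the session schedule."""


@dataclass(frozen=True)
class ApneaInterval:
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("apnea interval must have end > start")

    def __contains__(self, t: float) -> bool:
        return self.start <= t <= self.end


@dataclass(frozen=True)
class SwallowEvent:
    """A detected swallow onset with its protocol labels."""

    onset: float
    apnea: ApneaInterval
    block: int | None = None
    position: str | None = None
    ordinal: int | None = None       # 1-based rank within its position segment
    verified: bool = False


# ---------------------------------------------------------------------------
# apnea detection from respiration
# ---------------------------------------------------------------------------

def detect_apnea(resp: np.ndarray, sample_rate: float = RESP_RATE,
                 deriv_threshold_fraction: float = 0.1,
                 min_duration_s: float = 0.75,
                 smooth_window_s: float = 0.2) -> list[ApneaInterval]:
    """Find maximal intervals where breathing flow is near zero.

    The smoothed respiratory derivative is compared against a threshold
    set at ``deriv_threshold_fraction`` of the median absolute derivative
    of the whole record; stretches below threshold lasting at least
    ``min_duration_s`` are returned as apneas.  A constant record (no
    breathing at all) degenerates to a single full-length apnea and a
    warning.
    """
    resp = np.asarray(resp, dtype=float)
    if not np.all(np.isfinite(resp)):
        raise ValueError("respiration signal contains non-finite values")
    if len(resp) < max(2, int(min_duration_s * sample_rate)):
        raise ValueError("record shorter than the minimum apnea duration")

    deriv = np.gradient(resp, 1.0 / sample_rate)
    n_w = int(round(smooth_window_s * sample_rate)) | 1    # force odd
    w = triang(n_w)
    w /= w.sum()
    padded = np.pad(deriv, n_w // 2, mode="reflect")
    smooth = oaconvolve(padded, w, mode="valid")

    threshold = deriv_threshold_fraction * np.median(np.abs(smooth))
    if threshold == 0.0:
        warnings.warn("respiration record is constant; treating the whole "
                      "record as one apnea", stacklevel=2)
        return [ApneaInterval(0.0, len(resp) / sample_rate)]

    below = np.abs(smooth) < threshold
    edges = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if below[0]:
        starts = np.r_[0, starts]
    if below[-1]:
        ends = np.r_[ends, len(below)]
    min_samples = int(min_duration_s * sample_rate)
    return [ApneaInterval(s / sample_rate, e / sample_rate)
            for s, e in zip(starts, ends) if e - s >= min_samples]


# ---------------------------------------------------------------------------
# accelerometer envelope and derivative
# ---------------------------------------------------------------------------

def envelope(accel: np.ndarray, window: int = 201) -> np.ndarray:
    """Rectify and smooth with a zero-lag triangular (Bartlett) window.

    The window has ``window`` taps with weights summing to one (centre
    tap 2/(N+1)); edges are handled by reflection so a constant input
    maps to a constant output of the same length.
    """
    if window % 2 == 0 or window < 3:
        raise ConfigurationError("window length must be odd and >= 3")
    x = np.abs(np.asarray(accel, dtype=float))
    w = triang(window)
    w /= w.sum()
    padded = np.pad(x, window // 2, mode="reflect")
    return oaconvolve(padded, w, mode="valid")


def derivative(env: np.ndarray, sample_rate: float = ACCEL_RATE) -> np.ndarray:
    """Central first difference scaled to per-second units.

    Interior samples use the symmetric two-sample stencil; the endpoints
    fall back to one-sided differences.
    """
    env = np.asarray(env, dtype=float)
    if len(env) < 2:
        raise ValueError("need at least two samples")
    return np.gradient(env, 1.0 / sample_rate)


# ---------------------------------------------------------------------------
# onset detection
# ---------------------------------------------------------------------------

def detect_onsets(deriv: np.ndarray, apneas: list[ApneaInterval],
                  sample_rate: float = ACCEL_RATE,
                  refractory_s: float = 2.0,
                  persistence_samples: int = 25) -> list[float]:
    """First sustained positive zero-crossing of the derivative per apnea.

    A candidate is a sample where the derivative moves from <= 0 to > 0
    and stays positive for ``persistence_samples`` samples; the first
    candidate inside each apnea is kept (at most one onset per apnea).
    Onsets closer together than ``refractory_s`` are deduplicated,
    keeping the earlier.
    """
    deriv = np.asarray(deriv, dtype=float)
    n = len(deriv)
    onsets: list[float] = []
    for ap in apneas:
        i0 = max(int(np.ceil(ap.start * sample_rate)), 1)
        i1 = min(int(ap.end * sample_rate), n)
        if i1 - i0 < 2:
            continue
        seg = deriv[i0:i1]
        prev = deriv[i0 - 1:i1 - 1]
        crossings = np.flatnonzero((prev <= 0) & (seg > 0))
        for c in crossings:
            j = i0 + c
            run = deriv[j:j + persistence_samples]
            if len(run) == persistence_samples and np.all(run > 0):
                onsets.append(j / sample_rate)
                break
    onsets.sort()
    kept: list[float] = []
    for t in onsets:
        if not kept or t - kept[-1] >= refractory_s:
            kept.append(t)
    return kept


# ---------------------------------------------------------------------------
# condition assignment
# ---------------------------------------------------------------------------

def assign_conditions(onsets: list[float] | np.ndarray, schedule: Schedule,
                      apneas: list[ApneaInterval] | None = None,
                      ) -> list[SwallowEvent]:
    """Label each onset with block / position / ordinal from the schedule.

    Onsets falling inside an inter-block rest are kept but flagged
    ``verified=False`` (excluded downstream); an onset covered by neither
    a position segment nor a rest is an integrity error.  Segment
    membership uses half-open intervals [start, end).  Labelling is
    idempotent: it depends only on the onset times and the schedule.
    """
    apneas = apneas or []

    def apnea_for(t: float) -> ApneaInterval:
        for ap in apneas:
            if t in ap:
                return ap
        return ApneaInterval(t - 0.5, t + 1.0)

    events: list[SwallowEvent] = []
    per_segment: dict[int, list[float]] = {}
    for t in sorted(float(t) for t in onsets):
        seg_i = next((i for i, s in enumerate(schedule.segments)
                      if s.start <= t < s.end), None)
        if seg_i is None:
            if any(a <= t < b for a, b in schedule.rests) or (
                    t < schedule.segments[0].start or t >= schedule.segments[-1].end):
                events.append(SwallowEvent(onset=t, apnea=apnea_for(t),
                                           verified=False))
                continue
            raise IntegrityError(f"onset at {t:.2f} s lies outside every "
                                 "position segment and rest period")
        per_segment.setdefault(seg_i, []).append(t)
        seg = schedule.segments[seg_i]
        events.append(SwallowEvent(
            onset=t, apnea=apnea_for(t), block=seg.block,
            position=seg.position, ordinal=len(per_segment[seg_i]),
            verified=True))
    return events


def events_frame(events: list[SwallowEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "onset": e.onset, "block": e.block, "position": e.position,
        "ordinal": e.ordinal, "apnea_start": e.apnea.start,
        "apnea_end": e.apnea.end, "verified": e.verified} for e in events])


# ---------------------------------------------------------------------------
# end-to-end detector
# ---------------------------------------------------------------------------

def detect_swallows(session: SessionRecording,
                    envelope_window: int = 201,
                    deriv_threshold_fraction: float = 0.1,
                    min_apnea_s: float = 0.75,
                    refractory_s: float = 2.0,
                    persistence_samples: int = 25) -> list[SwallowEvent]:
    """Run the full detection chain on one session recording."""
    apneas = detect_apnea(session.resp, session.sample_rates["resp"],
                          deriv_threshold_fraction=deriv_threshold_fraction,
                          min_duration_s=min_apnea_s)
    env = envelope(session.accel, envelope_window)
    deriv = derivative(env, session.sample_rates["accel"])
    onsets = detect_onsets(deriv, apneas, session.sample_rates["accel"],
                           refractory_s=refractory_s,
                           persistence_samples=persistence_samples)
    return assign_conditions(onsets, session.schedule, apneas)


def evaluate_detection(events: list[SwallowEvent], truth_onsets: np.ndarray,
                       tolerance_s: float = 0.2) -> dict:
    """Match detections to ground-truth onsets (greedy nearest within tol).

    Returns sensitivity, false-detection count, and the worst absolute
    timing error over matched pairs.
    """
    truth = np.sort(np.asarray(truth_onsets, dtype=float))
    detected = np.array(sorted(e.onset for e in events))
    matched = np.zeros(len(truth), dtype=bool)
    errors: list[float] = []
    false = 0
    for t in detected:
        if len(truth) == 0:
            false += 1
            continue
        i = int(np.argmin(np.abs(truth - t)))
        if not matched[i] and abs(truth[i] - t) <= tolerance_s:
            matched[i] = True
            errors.append(abs(truth[i] - t))
        else:
            false += 1
    return {
        "n_true": len(truth),
        "n_detected": len(detected),
        "n_matched": int(matched.sum()),
        "sensitivity": float(matched.mean()) if len(truth) else float("nan"),
        "n_false": false,
        "max_error_s": float(max(errors)) if errors else float("nan"),
    }
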