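"""Refixation-saccade detection, removal (desaccading) and rates.

Detection runs on the *residual* eye velocity -- the eye trace minus a
moving-median slow-phase estimate -- because during visually enhanced VOR
the compensatory slow phase itself can reach ~100 deg/s, so a threshold on
the raw trace cannot isolate fast phases across frequencies.  The median
kernel is scaled to the half-cycle so it tracks the sinusoidal slow phase
while rejecting brief saccadic transients.

Desaccading replaces each detected interval by linear interpolation between
the samples just outside it, preserving the area-under-the-curve semantics
of the gain computation without overshoot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from . import kinematics
from .errors import AnalysisError, ParameterError

DEFAULT_THRESHOLD_DPS = 60.0
DEFAULT_MIN_DURATION_MS = 10.0
DEFAULT_REFRACTORY_MS = 20.0


@dataclass(frozen=True)
class SaccadeEvent:
    onset_sample: int
    offset_sample: int  # half-open, absolute recording indices
    peak_velocity_dps: float
    amplitude_deg: float
    direction: str  # "left" | "right"


def _fill_missing(eye: np.ndarray) -> np.ndarray:
    """Interpolate over non-finite samples (median filter cannot skip them)."""
    out = np.asarray(eye, dtype=float).copy()
    bad = ~np.isfinite(out)
    if bad.any():
        if bad.all():
            return np.zeros_like(out)
        idx = np.arange(len(out))
        out[bad] = np.interp(idx[bad], idx[~bad], out[~bad])
    return out


def slow_phase_estimate(eye: np.ndarray, sample_rate_hz: float,
                        half_cycle_duration_s: float) -> np.ndarray:
    """Moving-median slow-phase estimate over a half-cycle-scaled kernel."""
    if half_cycle_duration_s <= 0:
        raise ParameterError("half_cycle_duration_s must be positive")
    kernel = int(round(0.5 * half_cycle_duration_s * sample_rate_hz))
    kernel = max(3, kernel | 1)  # odd, >= 3
    return median_filter(_fill_missing(eye), size=kernel, mode="nearest")


def detect_saccades(window, rec=None,
                    threshold_dps: float = DEFAULT_THRESHOLD_DPS,
                    min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
                    refractory_ms: float = DEFAULT_REFRACTORY_MS,
                    hysteresis_dps: float = kinematics.DEFAULT_HYSTERESIS_DPS,
                    ) -> list[SaccadeEvent]:
    """Detect fast-phase events in the eye trace of an accepted window.

    Candidate events are runs where |residual| exceeds ``threshold_dps``
    for at least ``min_duration_ms``; events separated by less than
    ``refractory_ms`` merge; onsets/offsets are extended outward to where
    |residual| falls below threshold/3.
    """
    rec = rec if rec is not None else window.recording
    if threshold_dps <= 0:
        raise ParameterError("threshold_dps must be positive")
    fs = rec.sample_rate_hz
    s, e = window.start_sample, window.end_sample
    eye = rec.eye_velocity_dps[s:e]

    half_cycles = kinematics.segment_half_cycles(window, hysteresis_dps)
    if half_cycles:
        half_dur = float(np.median([hc.duration_s for hc in half_cycles]))
    else:
        half_dur = 1.0 / (2.0 * rec.intended_frequency_hz)
    slow = slow_phase_estimate(eye, fs, half_dur)
    resid = _fill_missing(eye) - slow
    resid[~np.isfinite(eye)] = 0.0

    min_samples = max(1, int(round(min_duration_ms / 1000.0 * fs)))
    refractory = refractory_ms / 1000.0 * fs
    above = np.abs(resid) > threshold_dps
    runs = _true_runs(above)
    runs = [(a, b) for a, b in runs if b - a >= min_samples]
    runs = _merge_close(runs, refractory)

    low = threshold_dps / 3.0
    extended = []
    for a, b in runs:
        while a > 0 and abs(resid[a - 1]) > low:
            a -= 1
        while b < len(resid) and abs(resid[b]) > low:
            b += 1
        extended.append((a, b))
    extended = _merge_close(extended, 1)

    events = []
    dt = 1.0 / fs
    for a, b in extended:
        seg = resid[a:b]
        area = float(np.trapezoid(seg, dx=dt))
        events.append(SaccadeEvent(
            onset_sample=s + int(a),
            offset_sample=s + int(b),
            peak_velocity_dps=float(np.max(np.abs(seg))),
            amplitude_deg=abs(area),
            direction="right" if area > 0 else "left",
        ))
    return events


def _true_runs(mask: np.ndarray):
    idx = np.nonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))[0]
    return list(zip(idx[0::2], idx[1::2]))


def _merge_close(runs, gap: int):
    merged: list[tuple[int, int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def desaccade(window, rec=None, events=()) -> np.ndarray:
    """Eye velocity over the window with saccade intervals interpolated away.

    Samples outside event intervals are returned unchanged (bitwise).
    """
    rec = rec if rec is not None else window.recording
    s, e = window.start_sample, window.end_sample
    out = rec.eye_velocity_dps[s:e].astype(float).copy()
    n = len(out)
    for ev in events:
        a, b = ev.onset_sample - s, ev.offset_sample - s
        if a < 0 or b > n or a >= b:
            raise AnalysisError(
                f"event [{ev.onset_sample}, {ev.offset_sample}) outside window [{s}, {e})")
        left = out[a - 1] if a > 0 else out[b] if b < n else 0.0
        right = out[b] if b < n else left
        out[a:b] = np.interp(np.arange(a, b), [a - 1, b], [left, right])
    return out


def saccade_rate(events, window) -> float:
    """Number of events per second of window duration."""
    duration = window.duration_s
    if duration <= 0:
        raise ParameterError("window duration must be positive")
    return len(events) / duration
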