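"""Area-under-the-curve VVOR / VOR-suppression gain.

Gain is the ratio of the absolute area under the (desaccaded) eye-velocity
trace to the absolute area under the head-velocity trace, integrated
trapezoidally over one half-cycle.  The unsigned formulation makes the
compensatory (opposite-sign) eye movement yield a positive gain for both
the VVOR (~1) and the suppressed reflex (~0-0.5).  Gains are computed per
half-cycle so direction attribution -- by the HEAD turn direction -- is
unambiguous, then averaged per direction and overall.

A floor on the head movement (peak |head| below 10 deg/s by default) skips
degenerate half-cycles instead of dividing by a near-zero area.

Both traces are smoothed with the same short moving-average kernel (25 ms
by default) before integration.  Because the kernel is identical for eye
and head, a noise-free compensatory trace still yields the exact gain; the
smoothing only suppresses the rectification bias that measurement noise
would otherwise add to the absolute-area integral when the slow-phase
velocity is small (low-frequency VOR suppression).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from . import kinematics, saccades
from .errors import AnalysisError, HeadMovementTooSmall, ParameterError

DEFAULT_HEAD_PEAK_FLOOR_DPS = 10.0
DEFAULT_SMOOTHING_MS = 25.0


@dataclass
class GainResult:
    """Per-recording outcome set."""

    test_type: str
    intended_frequency_hz: float
    actual_frequency_hz: float
    mean_peak_head_velocity_dps: float
    per_half_cycle_gains: list        # (direction, gain)
    gain_right: float
    gain_left: float
    gain_overall: float
    saccade_rate_per_s: float
    profile: kinematics.ProfileReport
    n_half_cycles: int = 0
    n_skipped_half_cycles: int = 0
    qc_flags: list = field(default_factory=list)


def auc_gain_half_cycle(head_segment: np.ndarray,
                        eye_segment: np.ndarray,
                        dt: float,
                        head_peak_floor_dps: float = DEFAULT_HEAD_PEAK_FLOOR_DPS,
                        ) -> float:
    """AUC gain of one half-cycle; raises HeadMovementTooSmall below the floor."""
    head = np.asarray(head_segment, dtype=float)
    eye = np.asarray(eye_segment, dtype=float)
    if head.shape != eye.shape or head.size < 3:
        raise ParameterError("segments must have equal length >= 3")
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if float(np.max(np.abs(head))) < head_peak_floor_dps:
        raise HeadMovementTooSmall(
            f"insufficient head movement (peak < {head_peak_floor_dps} deg/s)")
    head_area = float(np.trapezoid(np.abs(head), dx=dt))
    eye_area = float(np.trapezoid(np.abs(eye), dx=dt))
    return eye_area / head_area


def compute_gain_result(rec, window, half_cycles, events,
                        head_peak_floor_dps: float = DEFAULT_HEAD_PEAK_FLOOR_DPS,
                        smoothing_ms: float = DEFAULT_SMOOTHING_MS,
                        ) -> GainResult:
    """Assemble the per-recording outcomes from an accepted window.

    The eye trace is desaccaded once over the window, both traces are
    smoothed with the same kernel, and gains are then computed per
    half-cycle and attributed to the head-turn direction.
    """
    if not window.accepted:
        raise AnalysisError(f"window was rejected ({window.reason})")
    if not half_cycles:
        raise AnalysisError("no half-cycles to analyse")
    dt = 1.0 / rec.sample_rate_hz
    desaccaded = saccades.desaccade(window, rec, events)
    s = window.start_sample
    head_win = rec.head_velocity_dps[s:window.end_sample].astype(float)
    kernel = int(round(smoothing_ms / 1000.0 * rec.sample_rate_hz))
    if kernel > 1:
        head_win = uniform_filter1d(head_win, size=kernel, mode="nearest")
        desaccaded = uniform_filter1d(desaccaded, size=kernel, mode="nearest")

    per_gain: list[tuple[str, float]] = []
    skipped = 0
    for hc in half_cycles:
        a, b = hc.start_sample - s, hc.end_sample - s
        try:
            g = auc_gain_half_cycle(
                head_win[a:b], desaccaded[a:b], dt, head_peak_floor_dps)
        except HeadMovementTooSmall:
            skipped += 1
            continue
        per_gain.append((hc.direction, g))
    if not per_gain:
        raise AnalysisError("all half-cycles skipped: insufficient head movement")

    rights = [g for d, g in per_gain if d == "right"]
    lefts = [g for d, g in per_gain if d == "left"]
    every = [g for _, g in per_gain]
    qc = []
    if skipped:
        qc.append(f"skipped_half_cycles:{skipped}")
    return GainResult(
        test_type=rec.test_type,
        intended_frequency_hz=rec.intended_frequency_hz,
        actual_frequency_hz=kinematics.estimate_frequency(half_cycles),
        mean_peak_head_velocity_dps=kinematics.peak_velocity_summary(half_cycles).mean_dps,
        per_half_cycle_gains=per_gain,
        gain_right=float(np.mean(rights)) if rights else float("nan"),
        gain_left=float(np.mean(lefts)) if lefts else float("nan"),
        gain_overall=float(np.mean(every)),
        saccade_rate_per_s=saccades.saccade_rate(events, window),
        profile=kinematics.classify_profile(window),
        n_half_cycles=len(per_gain),
        n_skipped_half_cycles=skipped,
        qc_flags=qc,
    )
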