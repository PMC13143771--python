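"""Artifact flagging and analysis-window selection.

A quantifiable window must capture at least five rotation cycles, contain
no artifact-flagged sample, and avoid the ramp-up/ramp-down of the rotation
("intermediate interval" rule): one full cycle adjacent to each quiet span
of the head trace is discarded by default.  Trimming is keyed to the head's
moving period, not to artifact runs, so adding artifact flags can only
shrink or reject the window, and re-selecting inside an accepted window is
a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d

from . import kinematics
from .errors import ParameterError
from .vog_io import Recording

DEFAULT_SPIKE_THRESHOLD_DPS = 800.0
DEFAULT_PAD_MS = 50.0
DEFAULT_MIN_CYCLES = 5
DEFAULT_TRIM_EDGE_CYCLES = 1
DEFAULT_MOVE_THRESHOLD_DPS = 10.0


@dataclass(frozen=True)
class ArtifactInterval:
    start_sample: int
    end_sample: int  # half-open
    reason: str      # "track_loss" | "blink_spike" | "user_excluded"


@dataclass
class ArtifactMask:
    mask: np.ndarray
    intervals: list[ArtifactInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.mask)


@dataclass
class AnalysisWindow:
    """Contiguous artifact-free span selected for quantification."""

    recording: Recording
    start_sample: int
    end_sample: int  # half-open
    n_cycles: int
    artifact_free: bool
    accepted: bool
    reason: str | None = None  # failure reason when not accepted

    @property
    def duration_s(self) -> float:
        return (self.end_sample - self.start_sample) / self.recording.sample_rate_hz


def _runs(mask: np.ndarray):
    """(start, end) half-open runs of True in a boolean array."""
    idx = np.nonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))[0]
    return list(zip(idx[0::2], idx[1::2]))


def flag_artifacts(rec: Recording,
                   spike_threshold_dps: float = DEFAULT_SPIKE_THRESHOLD_DPS,
                   pad_ms: float = DEFAULT_PAD_MS) -> ArtifactMask:
    """Flag untracked samples and supra-physiologic eye-velocity spikes.

    Missing samples are flagged as ``track_loss``; samples whose |eye
    velocity| exceeds ``spike_threshold_dps`` (beyond the voluntary range,
    so only blink artifacts trip it) as ``blink_spike``.  Every flagged
    interval is padded by ``pad_ms`` on both sides.
    """
    if spike_threshold_dps <= 0:
        raise ParameterError("spike_threshold_dps must be positive")
    n = len(rec)
    pad = int(round(pad_ms / 1000.0 * rec.sample_rate_hz))
    mask = np.zeros(n, dtype=bool)
    intervals: list[ArtifactInterval] = []
    eye = rec.eye_velocity_dps
    spikes = np.zeros(n, dtype=bool)
    finite = np.isfinite(eye)
    spikes[finite] = np.abs(eye[finite]) > spike_threshold_dps
    for reason, base in (("track_loss", rec.missing_mask.copy()),
                         ("blink_spike", spikes)):
        for a, b in _runs(base):
            a2, b2 = max(0, a - pad), min(n, b + pad)
            mask[a2:b2] = True
            intervals.append(ArtifactInterval(int(a2), int(b2), reason))
    intervals.sort(key=lambda iv: (iv.start_sample, iv.end_sample))
    return ArtifactMask(mask=mask, intervals=intervals)


def _moving_period(rec: Recording, move_threshold_dps: float) -> tuple[int, int] | None:
    """Half-open span over which the head is oscillating."""
    speed = np.abs(np.where(np.isfinite(rec.head_velocity_dps),
                            rec.head_velocity_dps, 0.0))
    width = max(3, int(round(0.6 * rec.sample_rate_hz / rec.intended_frequency_hz)))
    envelope = maximum_filter1d(speed, size=width, mode="nearest")
    moving = envelope >= move_threshold_dps
    idx = np.nonzero(moving)[0]
    if idx.size == 0:
        return None
    return int(idx[0]), int(idx[-1]) + 1


def select_window(rec: Recording,
                  mask: ArtifactMask,
                  min_cycles: int = DEFAULT_MIN_CYCLES,
                  trim_edge_cycles: int = DEFAULT_TRIM_EDGE_CYCLES,
                  hysteresis_dps: float = kinematics.DEFAULT_HYSTERESIS_DPS,
                  move_threshold_dps: float = DEFAULT_MOVE_THRESHOLD_DPS,
                  ) -> AnalysisWindow:
    """Select the longest artifact-free intermediate span of >= min_cycles.

    Returns a rejected window (``accepted`` False, with ``reason``) rather
    than raising when the recording cannot satisfy the criteria.
    """
    if min_cycles < 1:
        raise ParameterError("min_cycles must be >= 1")
    if len(mask) != len(rec):
        raise ParameterError("mask length does not match recording")
    n = len(rec)

    def rejected(reason: str, artifact_free: bool = True) -> AnalysisWindow:
        return AnalysisWindow(rec, 0, n, 0, artifact_free=artifact_free,
                              accepted=False, reason=reason)

    period = _moving_period(rec, move_threshold_dps)
    if period is None:
        return rejected("no_motion")
    m0, m1 = period
    head = rec.head_velocity_dps[m0:m1]
    crossings = kinematics.hysteresis_crossings(head, hysteresis_dps) + m0
    n_half = len(crossings) - 1
    if n_half < 1:
        return rejected("no_crossings")

    # "intermediate interval": drop full cycles adjacent to quiet spans
    trim_start = 2 * trim_edge_cycles if m0 > 0 else 0
    trim_end = 2 * trim_edge_cycles if m1 < n else 0
    if n_half - trim_start - trim_end < 2 * min_cycles:
        trim_start = trim_end = 0  # keep everything; may still reject below
    lo, hi = trim_start, n_half - trim_end
    if hi - lo < 1:
        return rejected("min_cycles")

    # longest run of consecutive half-cycles free of flagged samples
    clean = np.zeros(hi - lo, dtype=bool)
    for j, i in enumerate(range(lo, hi)):
        a = int(np.floor(crossings[i]))
        b = int(np.ceil(crossings[i + 1])) + 1
        clean[j] = not mask.mask[max(a, 0):min(b, n)].any()
    best = max(_runs(clean), key=lambda r: r[1] - r[0], default=None)
    if best is None:
        return rejected("artifacts", artifact_free=False)
    ra, rb = best[0] + lo, best[1] + lo  # half-cycle index range
    n_cycles = (rb - ra) // 2
    if n_cycles < min_cycles:
        if n_half // 2 >= min_cycles or (hi - lo) // 2 >= min_cycles:
            return rejected("artifacts", artifact_free=False)
        return rejected("min_cycles")

    start = max(0, int(np.floor(crossings[ra])))
    end = min(n, int(np.ceil(crossings[rb])) + 1)
    return AnalysisWindow(rec, start, end, int(n_cycles),
                          artifact_free=True, accepted=True)
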