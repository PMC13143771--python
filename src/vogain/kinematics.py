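"""Half-cycle segmentation and head-movement kinematics.

A half-cycle is one unidirectional sweep of the head, bounded by head
velocity zero crossings.  Crossings are located with a +/-hysteresis band so
measurement noise near zero does not create spurious cycles, and the actual
crossing instant is refined by linear interpolation between the bracketing
samples, giving sub-sample period accuracy at modest sample rates.

The actual rotation frequency is 1 / (2 * median half-cycle duration) -- the
median makes the estimate robust to a single hesitant cycle.  A spectral
peak is available as an independent cross-check diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ParameterError

DEFAULT_HYSTERESIS_DPS = 5.0
DEFAULT_R2_THRESHOLD = 0.90
DEFAULT_DISTORTION_THRESHOLD = 0.10


@dataclass(frozen=True)
class HalfCycle:
    """Zero-crossing-bounded half oscillation of the head trace.

    Sample indices are absolute recording indices, half-open; ``duration_s``
    uses the interpolated crossing instants, not the sample grid.
    """

    start_sample: int
    end_sample: int
    direction: str  # "left" | "right"
    peak_head_velocity_dps: float
    duration_s: float


@dataclass(frozen=True)
class PeakVelocitySummary:
    mean_dps: float
    right_mean_dps: float
    left_mean_dps: float


@dataclass(frozen=True)
class ProfileReport:
    fitted_frequency_hz: float
    sinusoid_fit_r2: float
    harmonic_distortion: float
    label: str  # "sinusoidal" | "square" | "jerky"


def hysteresis_crossings(v: np.ndarray, hysteresis_dps: float) -> np.ndarray:
    """Interpolated zero-crossing positions (float sample units) of ``v``.

    A crossing is only registered once the signal has travelled from beyond
    one hysteresis bound to beyond the other; its position is the linearly
    interpolated sign change closest to the departure from the previous
    regime.  The crossing that precedes the first armed excursion is
    recovered by a backward scan so that a window starting right at a
    crossing segments identically to the full trace.
    """
    v = np.asarray(v, dtype=float)
    h = float(hysteresis_dps)
    if h < 0:
        raise ParameterError("hysteresis must be non-negative")
    crossings: list[float] = []
    state = 0
    for i in range(len(v)):
        x = v[i]
        if not np.isfinite(x):
            continue
        if state == 0:
            if x > h or x < -h:
                state = 1 if x > h else -1
                c = _backward_crossing(v, i, state)
                if c is not None:
                    crossings.append(c)
        elif state == 1 and x < -h:
            crossings.append(_last_sign_change(v, i, falling=True))
            state = -1
        elif state == -1 and x > h:
            crossings.append(_last_sign_change(v, i, falling=False))
            state = 1
    if state != 0:
        c = _forward_crossing(v, state)
        if c is not None and (not crossings or c > crossings[-1]):
            crossings.append(c)
    return np.asarray(crossings, dtype=float)


def _interp_crossing(v: np.ndarray, k: int) -> float:
    a, b = v[k], v[k + 1]
    if a == b:
        return float(k)
    return k + a / (a - b)


def _last_sign_change(v: np.ndarray, i: int, falling: bool) -> float:
    """Position of the last sign change before index ``i`` (exclusive)."""
    k = i - 1
    if falling:
        while k >= 0 and not (np.isfinite(v[k]) and v[k] > 0):
            k -= 1
    else:
        while k >= 0 and not (np.isfinite(v[k]) and v[k] < 0):
            k -= 1
    k = max(k, 0)
    return _interp_crossing(v, k)


def _backward_crossing(v: np.ndarray, i: int, state: int) -> float | None:
    """Initial crossing before the first armed sample, if present."""
    k = i - 1
    while k >= 0:
        if np.isfinite(v[k]) and v[k] * state <= 0:
            return _interp_crossing(v, k)
        k -= 1
    return None


def _forward_crossing(v: np.ndarray, state: int) -> float | None:
    """Final crossing after the last armed excursion, if the trace returns
    through zero before ending (mirror of the backward scan, so a window
    ending right at a crossing segments identically to the full trace)."""
    h_idx = None
    for k in range(len(v) - 1, -1, -1):
        if np.isfinite(v[k]) and v[k] * state > 0:
            h_idx = k
            break
    if h_idx is None:
        return None
    for k in range(h_idx, len(v) - 1):
        if (np.isfinite(v[k]) and np.isfinite(v[k + 1])
                and v[k] * state > 0 and v[k + 1] * state <= 0):
            return _interp_crossing(v, k)
    return None


def segment_half_cycles(window, hysteresis_dps: float = DEFAULT_HYSTERESIS_DPS):
    """Segment the window's head trace into alternating half-cycles.

    Incomplete leading/trailing half-cycles (not bounded by crossings on
    both sides) are dropped.  Returns an empty list when no crossings exist
    (e.g. constant-sign velocity); the caller decides how to reject.
    """
    rec = window.recording
    v = rec.head_velocity_dps[window.start_sample:window.end_sample]
    fs = rec.sample_rate_hz
    crossings = hysteresis_crossings(v, hysteresis_dps)
    out: list[HalfCycle] = []
    for c0, c1 in zip(crossings[:-1], crossings[1:]):
        start = int(np.floor(c0)) + 1
        end = int(np.floor(c1)) + 1
        if end - start < 2:
            continue
        seg = v[start:end]
        peak_idx = int(np.nanargmax(np.abs(seg)))
        direction = "right" if seg[peak_idx] > 0 else "left"
        out.append(HalfCycle(
            start_sample=window.start_sample + start,
            end_sample=window.start_sample + end,
            direction=direction,
            peak_head_velocity_dps=float(abs(seg[peak_idx])),
            duration_s=float((c1 - c0) / fs),
        ))
    return out


def estimate_frequency(half_cycles) -> float:
    """Actual rotation frequency from the median half-cycle duration."""
    if len(half_cycles) < 2:
        raise InsufficientDataError("need at least 2 half-cycles to estimate frequency")
    durations = np.array([hc.duration_s for hc in half_cycles])
    return float(1.0 / (2.0 * np.median(durations)))


def spectral_peak_hz(signal: np.ndarray, sample_rate_hz: float) -> float:
    """Frequency of the largest non-DC spectral peak (diagnostic cross-check)."""
    x = np.asarray(signal, dtype=float)
    x = np.where(np.isfinite(x), x, 0.0)
    if len(x) < 8:
        raise InsufficientDataError("signal too short for a spectral estimate")
    x = (x - x.mean()) * np.hanning(len(x))
    spec = np.abs(np.fft.rfft(x))
    spec[0] = 0.0
    freqs = np.fft.rfftfreq(len(x), d=1.0 / sample_rate_hz)
    return float(freqs[int(np.argmax(spec))])


def peak_velocity_summary(half_cycles) -> PeakVelocitySummary:
    """Mean absolute peak head velocity, overall and by head-turn direction."""
    if not half_cycles:
        raise InsufficientDataError("no half-cycles")
    peaks = np.array([hc.peak_head_velocity_dps for hc in half_cycles])
    right = np.array([hc.peak_head_velocity_dps for hc in half_cycles
                      if hc.direction == "right"])
    left = np.array([hc.peak_head_velocity_dps for hc in half_cycles
                     if hc.direction == "left"])
    return PeakVelocitySummary(
        mean_dps=float(peaks.mean()),
        right_mean_dps=float(right.mean()) if right.size else float("nan"),
        left_mean_dps=float(left.mean()) if left.size else float("nan"),
    )


def _mean_half_cycle_waveform(v: np.ndarray, half_cycles, window_start: int,
                              n_grid: int = 64) -> np.ndarray:
    """Coherent average of the half-cycle waveform on a normalized phase grid.

    Each half-cycle is resampled to phase in [0, 1] and sign-aligned before
    averaging, so cycle-to-cycle pacing jitter does not decohere the shape
    and uncorrelated perturbations average out.
    """
    grid = np.linspace(0.0, 1.0, n_grid)
    acc = np.zeros(n_grid)
    for hc in half_cycles:
        seg = v[hc.start_sample - window_start:hc.end_sample - window_start]
        seg = np.where(np.isfinite(seg), seg, 0.0)
        phase = np.linspace(0.0, 1.0, len(seg))
        sign = 1.0 if hc.direction == "right" else -1.0
        acc += sign * np.interp(grid, phase, seg)
    return acc / len(half_cycles)


def _harmonic_powers(mean_wave: np.ndarray, n_harmonics: int = 5) -> np.ndarray:
    """Power at half-cycle harmonics 1..n (sin(k*pi*phase) basis).

    Harmonic k of the half-cycle shape oscillates at k times the rotation
    frequency; shapes symmetric within the half-cycle (sinusoid, square
    plateau) carry only odd k.
    """
    grid = np.linspace(0.0, 1.0, len(mean_wave))
    X = np.column_stack([np.sin(k * np.pi * grid)
                         for k in range(1, n_harmonics + 1)])
    beta, *_ = np.linalg.lstsq(X, mean_wave, rcond=None)
    return beta ** 2


def classify_profile(window,
                     hysteresis_dps: float = DEFAULT_HYSTERESIS_DPS,
                     r2_threshold: float = DEFAULT_R2_THRESHOLD,
                     distortion_threshold: float = DEFAULT_DISTORTION_THRESHOLD,
                     ) -> ProfileReport:
    """Label the head-movement profile as sinusoidal, square or jerky.

    A single least-squares sinusoid at the cycle-period frequency measures
    goodness of the sinusoidal profile (r2); harmonic distortion is the
    energy of harmonics 2-5 relative to the fundamental, measured on the
    cycle-averaged (phase-aligned) waveform so pacing jitter and random
    hesitations do not masquerade as harmonic structure.  A distorted
    profile dominated by odd harmonics is the signature of a square
    (plateau-velocity) rotation; a poorly fitting profile without that
    signature is labelled jerky.
    """
    rec = window.recording
    half_cycles = segment_half_cycles(window, hysteresis_dps)
    if len(half_cycles) < 2:
        return ProfileReport(float("nan"), 0.0, float("inf"), "jerky")
    f = estimate_frequency(half_cycles)
    v = rec.head_velocity_dps[window.start_sample:window.end_sample]
    good = np.isfinite(v)
    t = np.arange(window.start_sample, window.end_sample) / rec.sample_rate_hz
    t, v = t[good], v[good]

    X1 = np.column_stack([np.ones_like(t),
                          np.sin(2 * np.pi * f * t),
                          np.cos(2 * np.pi * f * t)])
    beta, *_ = np.linalg.lstsq(X1, v, rcond=None)
    resid = v - X1 @ beta
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)

    v_all = rec.head_velocity_dps[window.start_sample:window.end_sample]
    mean_wave = _mean_half_cycle_waveform(v_all, half_cycles, window.start_sample)
    powers = _harmonic_powers(mean_wave)
    fundamental = powers[0]
    hd = float(powers[1:].sum() / fundamental) if fundamental > 0 else float("inf")
    odd = powers[2] + powers[4]     # harmonics 3 and 5
    even = powers[1] + powers[3]    # harmonics 2 and 4

    if hd > distortion_threshold and odd > even:
        label = "square"
    elif r2 >= r2_threshold and hd <= distortion_threshold:
        label = "sinusoidal"
    else:
        label = "jerky"
    return ProfileReport(fitted_frequency_hz=f, sinusoid_fit_r2=r2,
                         harmonic_distortion=hd, label=label)
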