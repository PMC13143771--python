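"""Synthetic video-oculography cohorts with known ground truth.

The generator emulates a metronome-paced manual rotation protocol: the head
trace is a concatenation of half-cycles, each a half-sine (or smoothed
trapezoid for the "square" profile) whose period is drawn from a jittered
pacing model around the commanded frequency and whose velocity peak follows
Vpeak = 2*pi*f*A for a per-side amplitude A drawn near 14-18.5 degrees.

Slow-phase eye velocity is -g * head velocity plus measurement noise, with
the true gain g given by the test-specific law:

* VVOR: g = vvor_gain_base +/- direction_asymmetry(f)/2 by head-turn
  direction (rightward half-cycles higher), so the right-left difference
  equals the asymmetry and the grand mean equals the base.
* VOR suppression: g = vors_gain_floor + vors_slope_per_hz * max(0, f -
  vors_knee_hz), plus a small per-decade age slope.

Refixation saccades are raised-cosine velocity pulses whose displacement
cancels a fraction of the current gaze-position error (relative to the
earth-fixed target for VVOR, to the head-fixed target for VOR suppression);
their duration follows a main-sequence rule.  Blink artifacts are inserted
as 100-300 ms spans of missing eye data.  Every injected quantity is
returned in a :class:`GroundTruth` so analyses can be validated by
parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import DataError, ParameterError
from .vog_io import Recording

#: default rightward VVOR gain excess by frequency (interpolated in between)
DEFAULT_VVOR_ASYMMETRY = {0.25: 0.154, 0.50: 0.125, 0.75: 0.096,
                          1.00: 0.066, 1.25: 0.037}

#: expected refixation-saccade rates (events/s) by test type and frequency
DEFAULT_SACCADE_RATES = {
    "VVOR": {0.25: 0.11, 0.50: 0.15, 0.75: 0.19, 1.00: 0.24, 1.25: 0.29},
    "VORS": {0.25: 1.10, 0.50: 1.80, 0.75: 3.00, 1.00: 3.30, 1.25: 3.40},
}


@dataclass
class SimCohortParams:
    """Cohort-level generative parameters (defaults emulate the protocol)."""

    n_participants: int = 24
    age_range_years: tuple[float, float] = (20.0, 79.0)
    frequency_levels_hz: tuple[float, ...] = (0.25, 0.50, 0.75, 1.00, 1.25)
    amplitude_deg_range: tuple[float, float] = (14.0, 18.5)
    amplitude_rel_jitter: float = 0.05       # per-half-cycle amplitude wobble
    pacing_jitter_sd_hz: float = 0.01        # per-half-cycle frequency jitter
    tempo_bias_sd_hz: float = 0.008          # per-recording metronome tempo error
    velocity_noise_sd_dps: float = 2.0       # additive slow-phase noise
    vvor_gain_base: float = 1.0
    direction_asymmetry: float | dict = field(
        default_factory=lambda: dict(DEFAULT_VVOR_ASYMMETRY))
    direction_asymmetry_sd: float = 0.02     # between-participant spread
    vors_gain_floor: float = 0.20
    vors_knee_hz: float = 0.50
    vors_slope_per_hz: float = 0.36
    vors_slope_sd: float = 0.05              # between-participant slope spread
    vors_age_slope_per_decade: float = 0.008
    participant_gain_sd: float = 0.02        # random intercept across participants
    saccade_rate_model: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SACCADE_RATES.items()})
    saccade_correction_fraction: float = 0.8
    min_saccade_amplitude_deg: float = 1.5
    max_saccade_amplitude_deg: float = 12.0
    blink_rate_per_min: float = 0.5
    profile_type: str = "sinusoidal"         # "sinusoidal" | "square" | "jerky"
    square_rise_fraction: float = 0.10
    jerky_perturbation_fraction: float = 0.30
    duration_s: float = 30.0
    lead_in_s: float = 0.5
    lead_out_s: float = 0.5
    sample_rate_hz: float = 220.0
    vhit_gain_mean: float = 0.97
    vhit_gain_sd: float = 0.05
    seed: int = 0

    def validate(self) -> "SimCohortParams":
        if self.n_participants < 1:
            raise ParameterError("n_participants must be positive")
        lo, hi = self.amplitude_deg_range
        if not (0 < lo <= hi < 90):
            raise ParameterError("amplitude range must lie within (0, 90) degrees")
        if list(self.frequency_levels_hz) != sorted(self.frequency_levels_hz):
            raise ParameterError("frequency_levels_hz must be sorted ascending")
        if min(self.frequency_levels_hz) <= 0:
            raise ParameterError("frequencies must be positive")
        for name in ("pacing_jitter_sd_hz", "velocity_noise_sd_dps",
                     "vvor_gain_base", "vors_gain_floor", "vors_slope_per_hz",
                     "blink_rate_per_min", "participant_gain_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.profile_type not in ("sinusoidal", "square", "jerky"):
            raise ParameterError(f"unknown profile_type {self.profile_type!r}")
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ParameterError("duration and sample rate must be positive")
        return self

    def asymmetry_at(self, frequency_hz: float) -> float:
        if isinstance(self.direction_asymmetry, dict):
            freqs = sorted(self.direction_asymmetry)
            vals = [self.direction_asymmetry[f] for f in freqs]
            return float(np.interp(frequency_hz, freqs, vals))
        return float(self.direction_asymmetry)

    def saccade_rate_at(self, test_type: str, frequency_hz: float) -> float:
        model = self.saccade_rate_model.get(test_type, {})
        if not model:
            return 0.0
        freqs = sorted(model)
        vals = [model[f] for f in freqs]
        return float(np.interp(frequency_hz, freqs, vals))

    def true_slow_phase_gain(self, test_type: str, frequency_hz: float,
                             direction: str, age_years: float = 0.0,
                             age_center_years: float = 0.0,
                             participant_offset: float = 0.0,
                             participant_asymmetry_offset: float = 0.0,
                             participant_slope_offset: float = 0.0) -> float:
        """The injected slow-phase gain law."""
        if test_type == "VVOR":
            g = self.vvor_gain_base + participant_offset
            half = 0.5 * (self.asymmetry_at(frequency_hz)
                          + participant_asymmetry_offset)
            g += half if direction == "right" else -half
        elif test_type == "VORS":
            g = (self.vors_gain_floor
                 + (self.vors_slope_per_hz + participant_slope_offset)
                 * max(0.0, frequency_hz - self.vors_knee_hz)
                 + self.vors_age_slope_per_decade
                 * (age_years - age_center_years) / 10.0
                 + participant_offset)
        else:
            raise ParameterError(f"no gain law for test_type {test_type!r}")
        return max(g, 0.0)


@dataclass
class GroundTruth:
    """Everything that was injected into one simulated recording."""

    gain_right: float
    gain_left: float
    cycle_frequencies_hz: np.ndarray       # per half-cycle
    peak_head_velocities_dps: np.ndarray   # per half-cycle
    half_cycle_starts_s: np.ndarray
    half_cycle_directions: list
    saccade_onsets_s: np.ndarray
    saccade_durations_s: np.ndarray
    saccade_amplitudes_deg: np.ndarray
    artifact_intervals_s: list             # (start_s, end_s) missing spans
    profile_type: str
    saccade_rate_per_s: float


def _recording_rng(seed: int, participant_index: int, test_type: str,
                   frequency_hz: float) -> np.random.Generator:
    """Deterministic per-recording stream so any subset is reproducible."""
    t_idx = {"VVOR": 0, "VORS": 1, "VHIT_SCREEN": 2}[test_type]
    f_key = int(round(frequency_hz * 1000))
    ss = np.random.SeedSequence(entropy=seed,
                                spawn_key=(participant_index, t_idx, f_key))
    return np.random.default_rng(ss)


def _half_cycle_waveform(phase: np.ndarray, profile: str, rise: float) -> np.ndarray:
    if profile == "square":
        ramp_up = np.clip(phase / rise, 0.0, 1.0)
        ramp_down = np.clip((1.0 - phase) / rise, 0.0, 1.0)
        return np.minimum(ramp_up, ramp_down)
    return np.sin(np.pi * phase)


def _waveform_area_fraction(profile: str, rise: float) -> float:
    """Integral of the unit waveform over one half-cycle of unit duration."""
    if profile == "square":
        return 1.0 - rise
    return 2.0 / math.pi


def simulate_recording(params: SimCohortParams, participant_id: str,
                       test_type: str, intended_frequency_hz: float,
                       rng: np.random.Generator,
                       age_years: float = 0.0,
                       age_center_years: float | None = None,
                       participant_offset: float = 0.0,
                       participant_asymmetry_offset: float = 0.0,
                       participant_slope_offset: float = 0.0,
                       ) -> tuple[Recording, GroundTruth]:
    """Generate one recording plus its ground truth.

    ``rng`` is consumed; use :func:`recording_rng` (or simulate_cohort) for
    reproducible per-recording streams.
    """
    params.validate()
    if intended_frequency_hz not in params.frequency_levels_hz:
        raise ParameterError(
            f"{intended_frequency_hz} Hz not in frequency_levels_hz")
    f0 = float(intended_frequency_hz)
    fs = params.sample_rate_hz
    motion_span = params.duration_s - params.lead_in_s - params.lead_out_s
    if motion_span < 5.0 / f0:
        raise ParameterError(
            f"duration {params.duration_s}s too short for 5 cycles at {f0} Hz")
    if age_center_years is None:
        age_center_years = 0.5 * sum(params.age_range_years)

    n = int(round(params.duration_s * fs))
    time = np.arange(n) / fs
    head = np.zeros(n)

    tempo_bias = rng.normal(0.0, params.tempo_bias_sd_hz)
    amp_center = rng.uniform(*params.amplitude_deg_range)
    sign = int(rng.choice([-1, 1]))
    profile = params.profile_type
    rise = params.square_rise_fraction
    area_frac = _waveform_area_fraction(
        "square" if profile == "square" else "sinusoidal", rise)

    # --- head trace: concatenated jittered half-cycles -------------------
    t = params.lead_in_s
    cycle_freqs, cycle_peaks, cycle_starts, cycle_dirs = [], [], [], []
    end_of_motion = params.duration_s - params.lead_out_s
    while True:
        f_i = f0 + tempo_bias + rng.normal(0.0, params.pacing_jitter_sd_hz)
        f_i = max(f_i, 0.25 * f0)
        half_dur = 1.0 / (2.0 * f_i)
        if t + half_dur > end_of_motion:
            break
        amp = amp_center * max(0.2, 1.0 + rng.normal(0.0, params.amplitude_rel_jitter))
        vpeak = 2.0 * amp / (half_dur * area_frac)  # sweeps 2*amp degrees
        i0, i1 = int(np.ceil(t * fs)), int(np.ceil((t + half_dur) * fs))
        i1 = min(i1, n)
        phase = (time[i0:i1] - t) / half_dur
        wave = _half_cycle_waveform(
            phase, "square" if profile == "square" else "sinusoidal", rise)
        head[i0:i1] = sign * vpeak * wave
        cycle_freqs.append(f_i)
        cycle_peaks.append(vpeak)
        cycle_starts.append(t)
        cycle_dirs.append("right" if sign > 0 else "left")
        t += half_dur
        sign = -sign

    if profile == "jerky":
        head = _add_jerk(head, params, fs, rng,
                         params.lead_in_s, t)

    # --- slow-phase eye trace -------------------------------------------
    gain_of = {
        d: params.true_slow_phase_gain(test_type, f0, d, age_years,
                                       age_center_years, participant_offset,
                                       participant_asymmetry_offset,
                                       participant_slope_offset)
        for d in ("right", "left")}
    g_per_sample = np.zeros(n)
    for start, f_i, d in zip(cycle_starts, cycle_freqs, cycle_dirs):
        i0 = int(np.ceil(start * fs))
        i1 = min(int(np.ceil((start + 1.0 / (2 * f_i)) * fs)), n)
        g_per_sample[i0:i1] = gain_of[d]
    slow_clean = -g_per_sample * head
    eye = slow_clean + (rng.normal(0.0, params.velocity_noise_sd_dps, n)
                        if params.velocity_noise_sd_dps > 0 else 0.0)

    # --- refixation saccades --------------------------------------------
    rate = params.saccade_rate_at(test_type, f0)
    onsets, durations, amplitudes = _inject_saccades(
        eye, slow_clean, head, time, fs, rate, rng, params,
        test_type, params.lead_in_s, t)

    # --- blink / track-loss artifacts ------------------------------------
    missing = np.zeros(n, dtype=bool)
    artifact_intervals = []
    if params.blink_rate_per_min > 0:
        t_blink = rng.exponential(60.0 / params.blink_rate_per_min)
        while t_blink < params.duration_s:
            dur = rng.uniform(0.1, 0.3)
            a = int(t_blink * fs)
            b = min(int((t_blink + dur) * fs), n)
            if b > a:
                missing[a:b] = True
                artifact_intervals.append((a / fs, b / fs))
            t_blink += dur + rng.exponential(60.0 / params.blink_rate_per_min)
    eye[missing] = np.nan

    rec = Recording(
        participant_id=participant_id,
        age_years=age_years,
        test_type=test_type,
        intended_frequency_hz=f0,
        sample_rate_hz=fs,
        time_s=time,
        head_velocity_dps=head,
        eye_velocity_dps=eye,
        missing_mask=missing,
    ).validate()
    truth = GroundTruth(
        gain_right=gain_of["right"],
        gain_left=gain_of["left"],
        cycle_frequencies_hz=np.asarray(cycle_freqs),
        peak_head_velocities_dps=np.asarray(cycle_peaks),
        half_cycle_starts_s=np.asarray(cycle_starts),
        half_cycle_directions=cycle_dirs,
        saccade_onsets_s=np.asarray(onsets),
        saccade_durations_s=np.asarray(durations),
        saccade_amplitudes_deg=np.asarray(amplitudes),
        artifact_intervals_s=artifact_intervals,
        profile_type=profile,
        saccade_rate_per_s=rate,
    )
    return rec, truth


def _add_jerk(head, params, fs, rng, t_start, t_end):
    """Low-frequency velocity perturbations over the moving span."""
    from scipy.signal import butter, filtfilt
    n = len(head)
    noise = rng.normal(0.0, 1.0, n)
    b, a = butter(2, 3.0 / (fs / 2.0), btype="low")
    smooth = filtfilt(b, a, noise)
    moving = np.zeros(n, dtype=bool)
    moving[int(t_start * fs):int(t_end * fs)] = True
    rms = float(np.sqrt(np.mean(smooth[moving] ** 2))) or 1.0
    peak = float(np.max(np.abs(head))) or 1.0
    out = head.copy()
    out[moving] += (params.jerky_perturbation_fraction * peak / rms
                    ) * smooth[moving]
    return out


def _inject_saccades(eye, slow_clean, head, time, fs, rate, rng, params,
                     test_type, t_start, t_end):
    """Add corrective velocity pulses; returns (onsets, durations, amps)."""
    if rate <= 0 or t_end - t_start <= 0.5:
        return [], [], []
    # gaze-position error rate: ideal eye velocity is -head (earth-fixed
    # target) for VVOR, 0 (head-fixed target) for VOR suppression
    ideal = -head if test_type == "VVOR" else np.zeros_like(head)
    err_rate = slow_clean - ideal
    base_err = np.concatenate(([0.0], np.cumsum(err_rate) / fs))[:-1]

    times = []
    t = t_start + rng.exponential(1.0 / rate)
    while t < t_end - 0.15:
        times.append(t)
        t += max(0.15, rng.exponential(1.0 / rate))
    onsets, durations, amps = [], [], []
    carried = 0.0
    n = len(eye)
    for t_on in times:
        i_on = int(round(t_on * fs))
        err = base_err[min(i_on, n - 1)] + carried
        disp = -params.saccade_correction_fraction * err
        if abs(disp) < params.min_saccade_amplitude_deg:
            s = np.sign(disp) if disp != 0 else rng.choice([-1.0, 1.0])
            disp = s * params.min_saccade_amplitude_deg
        disp = float(np.clip(disp, -params.max_saccade_amplitude_deg,
                             params.max_saccade_amplitude_deg))
        dur = float(np.clip(0.02 + 0.0025 * abs(disp), 0.02, 0.08))
        i_off = int(round((t_on + dur) * fs))
        if i_off >= n:
            break
        vpeak = 2.0 * disp / dur  # raised cosine integrates to disp
        seg = time[i_on:i_off]
        eye[i_on:i_off] += 0.5 * vpeak * (1.0 - np.cos(2 * np.pi * (seg - t_on) / dur))
        carried += disp
        onsets.append(t_on)
        durations.append(dur)
        amps.append(disp)
    return onsets, durations, amps


@dataclass
class CohortSim:
    params: SimCohortParams
    recordings: list           # list of (Recording, GroundTruth)
    manifest: dict


def recording_rng(params: SimCohortParams, participant_index: int,
                  test_type: str, frequency_hz: float) -> np.random.Generator:
    return _recording_rng(params.seed, participant_index, test_type, frequency_hz)


def simulate_cohort(params: SimCohortParams,
                    test_types: tuple[str, ...] = ("VVOR", "VORS"),
                    ) -> CohortSim:
    """One recording per participant x frequency level x test type.

    Ages are spread evenly over the age range; each participant gets a
    screening (vHIT) gain and a gain random intercept recorded in the
    manifest together with every injected parameter.
    """
    params.validate()
    np_ = params.n_participants
    ages = (np.linspace(*params.age_range_years, np_) if np_ > 1
            else np.array([np.mean(params.age_range_years)]))
    age_center = float(np.mean(ages))
    participants = []
    for p in range(np_):
        prng = np.random.default_rng(
            np.random.SeedSequence(entropy=params.seed, spawn_key=(p,)))
        participants.append({
            "participant_id": f"P{p + 1:02d}",
            "age_years": float(ages[p]),
            "sex": "M" if p % 2 == 0 else "F",
            "vhit_gain": float(np.clip(
                prng.normal(params.vhit_gain_mean, params.vhit_gain_sd),
                0.0, 1.3)),
            "gain_offset": float(prng.normal(0.0, params.participant_gain_sd)),
            "asymmetry_offset": float(
                prng.normal(0.0, params.direction_asymmetry_sd)),
            "slope_offset": float(prng.normal(0.0, params.vors_slope_sd)),
        })

    recordings = []
    rec_meta = []
    for p, part in enumerate(participants):
        for test_type in test_types:
            for f in params.frequency_levels_hz:
                rng = _recording_rng(params.seed, p, test_type, f)
                rec, truth = simulate_recording(
                    params, part["participant_id"], test_type, f, rng,
                    age_years=part["age_years"],
                    age_center_years=age_center,
                    participant_offset=part["gain_offset"],
                    participant_asymmetry_offset=part["asymmetry_offset"],
                    participant_slope_offset=part["slope_offset"])
                recordings.append((rec, truth))
                rec_meta.append({
                    "participant_id": part["participant_id"],
                    "test_type": test_type,
                    "intended_frequency_hz": f,
                    "true_gain_right": truth.gain_right,
                    "true_gain_left": truth.gain_left,
                    "true_saccade_rate_per_s": truth.saccade_rate_per_s,
                    "n_half_cycles": len(truth.cycle_frequencies_hz),
                })
    manifest = {
        "seed": params.seed,
        "age_center_years": age_center,
        "params": _params_to_manifest(params),
        "participants": participants,
        "recordings": rec_meta,
    }
    return CohortSim(params=params, recordings=recordings, manifest=manifest)


def _params_to_manifest(params: SimCohortParams) -> dict:
    out = asdict(params)
    for key, value in out.items():
        if isinstance(value, tuple):
            out[key] = list(value)
    return out


def screen_cohort(manifest: dict, threshold: float = 0.8) -> set[str]:
    """Participants passing the vHIT screen: gain strictly greater than threshold."""
    included = set()
    for part in manifest.get("participants", []):
        if "vhit_gain" not in part:
            raise DataError(
                f"participant {part.get('participant_id')!r} has no screening gain")
        if part["vhit_gain"] > threshold:
            included.add(part["participant_id"])
    return included


def match_saccades(detected, truth_onsets_s, sample_rate_hz: float,
                   tolerance_s: float = 0.05) -> tuple[int, int, int]:
    """Greedy one-to-one match of detected events to injected onsets.

    Returns (n_matched, n_detected, n_injected) for sensitivity / false
    discovery computations.
    """
    det_onsets = sorted(ev.onset_sample / sample_rate_hz for ev in detected)
    truth = sorted(float(t) for t in truth_onsets_s)
    matched = 0
    used = [False] * len(truth)
    for d in det_onsets:
        best, best_dt = None, tolerance_s
        for j, t in enumerate(truth):
            if used[j]:
                continue
            dt = abs(d - t)
            if dt <= best_dt:
                best, best_dt = j, dt
        if best is not None:
            used[best] = True
            matched += 1
    return matched, len(det_onsets), len(truth)
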