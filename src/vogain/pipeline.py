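"""Per-recording and cohort-level analysis orchestration."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gain as gain_mod
from . import kinematics, preprocess, saccades
from .config import AnalysisConfig
from .errors import AnalysisError
from .vog_io import Recording


@dataclass
class RecordingAnalysis:
    recording: Recording
    accepted: bool
    reason: str | None
    window: preprocess.AnalysisWindow | None = None
    events: list | None = None
    result: gain_mod.GainResult | None = None


def analyze_recording(rec: Recording,
                      config: AnalysisConfig | None = None) -> RecordingAnalysis:
    """Run the full pipeline on one recording.

    Stages: artifact flagging -> window selection -> half-cycle
    segmentation -> saccade detection -> desaccaded AUC gain.  A recording
    that fails window selection is reported as rejected, not raised.
    """
    cfg = config or AnalysisConfig()
    mask = preprocess.flag_artifacts(
        rec, cfg.preprocess.spike_threshold_dps, cfg.preprocess.pad_ms)
    window = preprocess.select_window(
        rec, mask,
        min_cycles=cfg.preprocess.min_cycles,
        trim_edge_cycles=cfg.preprocess.trim_edge_cycles,
        hysteresis_dps=cfg.kinematics.hysteresis_dps,
        move_threshold_dps=cfg.preprocess.move_threshold_dps)
    if not window.accepted:
        return RecordingAnalysis(rec, False, window.reason, window)
    half_cycles = kinematics.segment_half_cycles(
        window, cfg.kinematics.hysteresis_dps)
    events = saccades.detect_saccades(
        window, rec,
        threshold_dps=cfg.saccades.threshold_dps,
        min_duration_ms=cfg.saccades.min_duration_ms,
        refractory_ms=cfg.saccades.refractory_ms,
        hysteresis_dps=cfg.kinematics.hysteresis_dps)
    try:
        result = gain_mod.compute_gain_result(
            rec, window, half_cycles, events,
            head_peak_floor_dps=cfg.gain.head_peak_floor_dps,
            smoothing_ms=cfg.gain.smoothing_ms)
    except AnalysisError as exc:
        return RecordingAnalysis(rec, False, str(exc), window, events)
    return RecordingAnalysis(rec, True, None, window, events, result)


def cohort_table(recordings, config: AnalysisConfig | None = None
                 ) -> tuple[pd.DataFrame, list[RecordingAnalysis]]:
    """Analyse a collection of recordings into a long-format cohort table.

    One gain row per accepted recording x head-turn direction.  Rejected
    recordings are returned separately with their failure reason.
    """
    rows = []
    failures = []
    for rec in recordings:
        analysis = analyze_recording(rec, config)
        if not analysis.accepted:
            failures.append(analysis)
            continue
        res = analysis.result
        for direction, g in (("right", res.gain_right), ("left", res.gain_left)):
            if not np.isfinite(g):
                continue
            rows.append({
                "participant_id": rec.participant_id,
                "age_years": rec.age_years,
                "test_type": rec.test_type,
                "intended_frequency_hz": rec.intended_frequency_hz,
                "direction": direction,
                "gain": g,
                "saccade_rate_per_s": res.saccade_rate_per_s,
                "actual_frequency_hz": res.actual_frequency_hz,
                "mean_peak_head_velocity_dps": res.mean_peak_head_velocity_dps,
                "profile": res.profile.label,
                "n_half_cycles": res.n_half_cycles,
                "qc_flags": ";".join(res.qc_flags),
            })
    return pd.DataFrame(rows), failures
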