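import numpy as np
import pytest
from hypothesis import settings

from vogain.config import AnalysisConfig
from vogain.simulate import SimCohortParams, recording_rng, simulate_recording

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def clean_params(**overrides) -> SimCohortParams:
    """Deterministic, artifact-free generator settings for unit tests."""
    base = dict(
        velocity_noise_sd_dps=0.0,
        pacing_jitter_sd_hz=0.0,
        tempo_bias_sd_hz=0.0,
        amplitude_rel_jitter=0.0,
        direction_asymmetry=0.0,
        direction_asymmetry_sd=0.0,
        participant_gain_sd=0.0,
        saccade_rate_model={},
        blink_rate_per_min=0.0,
        seed=0,
    )
    base.update(overrides)
    return SimCohortParams(**base)


def make_recording(params=None, test_type="VVOR", frequency=1.0,
                   participant_index=0, age_years=49.5):
    params = params or clean_params()
    rng = recording_rng(params, participant_index, test_type, frequency)
    return simulate_recording(params, f"P{participant_index + 1:02d}",
                              test_type, frequency, rng, age_years=age_years)


@pytest.fixture
def default_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def clean_recording():
    """Noise-free 1 Hz VVOR recording with unity gain."""
    rec, truth = make_recording()
    return rec, truth


def sinusoid_recording(frequency=0.5, amplitude_deg=16.0, duration=20.0,
                       fs=220.0, gain=1.0, lead=1.0, noise_sd=0.0, seed=0):
    """Analytic sinusoidal recording (continuous phase, no generator)."""
    from vogain.vog_io import Recording

    n = int(duration * fs)
    t = np.arange(n) / fs
    vpeak = 2 * np.pi * frequency * amplitude_deg
    head = np.where((t >= lead) & (t < duration - lead),
                    vpeak * np.sin(2 * np.pi * frequency * (t - lead)), 0.0)
    rng = np.random.default_rng(seed)
    eye = -gain * head + (rng.normal(0, noise_sd, n) if noise_sd else 0.0)
    return Recording(
        participant_id="SYN", age_years=30.0, test_type="VVOR",
        intended_frequency_hz=frequency, sample_rate_hz=fs,
        time_s=t, head_velocity_dps=head, eye_velocity_dps=eye,
        missing_mask=np.zeros(n, dtype=bool),
    ).validate()
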