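"""Geometry of the metronome-paced rotation protocol.

The participant sits a fixed distance from a wall carrying two lateral
guide markers either side of a central fixation target.  The angle a marker
subtends at the nose bridge is atan(offset / distance); because the head's
rotation axis sits ~10 cm behind the nasion, the rotation angle about that
axis uses the longer effective distance and is slightly smaller.  For a
sinusoidal oscillation of amplitude A degrees per side at frequency f, the
peak head velocity is Vpeak = 2*pi*f*A (small-angle sinusoid, no spherical
correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ParameterError

PROTOCOL_FREQUENCIES_HZ = (0.25, 0.50, 0.75, 1.00, 1.25)


@dataclass(frozen=True)
class ProtocolGeometry:
    """Default values reproduce the published wall set-up (metres)."""

    viewing_distance_m: float = 1.30   # nasion to wall
    axis_offset_m: float = 0.10        # rotation axis behind the nasion
    marker_offsets_m: tuple[float, float] = (0.35, 0.47)  # inner, outer

    def __post_init__(self) -> None:
        if self.viewing_distance_m <= 0 or self.axis_offset_m < 0:
            raise ParameterError("distances must be positive (axis offset non-negative)")
        inner, outer = self.marker_offsets_m
        if not (0 < inner < outer):
            raise ParameterError("marker offsets must satisfy 0 < inner < outer")


def marker_angle(offset_m: float, distance_m: float) -> float:
    """Angle (degrees) a wall marker subtends at the given distance."""
    if distance_m <= 0:
        raise ParameterError("distance must be positive")
    if offset_m < 0:
        raise ParameterError("offset must be non-negative")
    return math.degrees(math.atan2(offset_m, distance_m))


def rotation_angle_range(geom: ProtocolGeometry) -> tuple[float, float]:
    """(min, max) head-rotation angle about the rotation axis, degrees.

    Uses effective distance = viewing distance + axis offset, so the range
    sits strictly inside the nasion-referenced marker angles whenever the
    axis offset is positive.
    """
    d = geom.viewing_distance_m + geom.axis_offset_m
    inner, outer = geom.marker_offsets_m
    return marker_angle(inner, d), marker_angle(outer, d)


def peak_velocity(frequency_hz: float, amplitude_deg: float) -> float:
    """Peak velocity (deg/s) of a sinusoid: 2*pi*f*A."""
    if frequency_hz < 0 or amplitude_deg < 0:
        raise ParameterError("frequency and amplitude must be non-negative")
    return 2.0 * math.pi * frequency_hz * amplitude_deg


def round_half_degree(angle_deg: float) -> float:
    """Round to the nearest half degree (display convention)."""
    return round(angle_deg * 2.0) / 2.0


def predicted_velocity_table(geom: ProtocolGeometry = ProtocolGeometry(),
                             frequency_levels_hz=PROTOCOL_FREQUENCIES_HZ,
                             ) -> pd.DataFrame:
    """Predicted peak-velocity band per protocol frequency level."""
    a_min, a_max = rotation_angle_range(geom)
    rows = [{"frequency_hz": f,
             "vpeak_min_dps": peak_velocity(f, a_min),
             "vpeak_max_dps": peak_velocity(f, a_max)}
            for f in frequency_levels_hz]
    return pd.DataFrame(rows)
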