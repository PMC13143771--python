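"""Reading and writing of head/eye velocity recordings.

The canonical on-disk form is a plain CSV with ``# key: value`` metadata
header lines followed by three columns ``time_s, head_velocity_dps,
eye_velocity_dps``.  Sign convention is fixed package-wide: rightward head
and eye rotation are positive, velocities are in degrees/second, and time is
0-based seconds from the start of the recording.  Samples whose velocity
cells are empty or non-numeric are kept (never dropped) and flagged in
``missing_mask``.

A tolerant ``otosuite_like`` dialect accepts device exports with extra
columns, loose column names and millisecond time stamps; recording metadata
may then live in a ``<file>.yaml`` sidecar.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError, ParameterError

TEST_TYPES = ("VVOR", "VORS", "VHIT_SCREEN")

#: metadata keys serialized into the canonical header
_META_KEYS = ("participant_id", "age_years", "test_type",
              "intended_frequency_hz", "sample_rate_hz")

_CANONICAL_COLUMNS = ("time_s", "head_velocity_dps", "eye_velocity_dps")


@dataclass
class Recording:
    """One test's synchronized head/eye velocity traces plus metadata.

    ``missing_mask`` marks samples whose eye image was lost (blink, track
    loss); the inertial head trace is typically still valid there.
    """

    participant_id: str
    age_years: float
    test_type: str
    intended_frequency_hz: float
    sample_rate_hz: float
    time_s: np.ndarray
    head_velocity_dps: np.ndarray
    eye_velocity_dps: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.head_velocity_dps = np.asarray(self.head_velocity_dps, dtype=float)
        self.eye_velocity_dps = np.asarray(self.eye_velocity_dps, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = ~(np.isfinite(self.head_velocity_dps)
                                  & np.isfinite(self.eye_velocity_dps))
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) + 1.0 / self.sample_rate_hz

    def validate(self) -> "Recording":
        """Check all container invariants; raise DataError/ParameterError."""
        n = len(self.time_s)
        if n < 2:
            raise DataError("recording must contain at least 2 samples")
        for name in ("head_velocity_dps", "eye_velocity_dps", "missing_mask"):
            if len(getattr(self, name)) != n:
                raise DataError(f"{name} length {len(getattr(self, name))} != time length {n}")
        if self.test_type not in TEST_TYPES:
            raise ParameterError(f"unknown test_type {self.test_type!r}")
        if not self.intended_frequency_hz > 0:
            raise ParameterError("intended_frequency_hz must be positive")
        if not self.sample_rate_hz > 0:
            raise ParameterError("sample_rate_hz must be positive")
        if self.age_years < 0:
            raise ParameterError("age_years must be non-negative")
        dt = np.diff(self.time_s)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise DataError(f"time_s not strictly increasing at row {int(bad[0]) + 1}")
        nominal = 1.0 / self.sample_rate_hz
        if abs(float(np.median(dt)) - nominal) > 0.01 * nominal:
            raise DataError("median sample interval inconsistent with sample_rate_hz")
        ok = ~self.missing_mask
        if not (np.isfinite(self.head_velocity_dps[ok]).all()
                and np.isfinite(self.eye_velocity_dps[ok]).all()):
            raise DataError("non-missing velocity values must be finite")
        return self


def write_recording(rec: Recording, path: str | os.PathLike) -> str:
    """Write ``rec`` as a canonical-dialect CSV; returns the path written.

    Non-finite velocity cells are serialized as empty fields so a
    write→read round trip reproduces both the values and the missing mask.
    """
    rec.validate()
    buf = io.StringIO()
    for key in _META_KEYS:
        buf.write(f"# {key}: {getattr(rec, key)}\n")
    buf.write(",".join(_CANONICAL_COLUMNS) + "\n")

    def cell(x: float) -> str:
        return "" if not math.isfinite(x) else format(x, ".9g")

    for t, h, e in zip(rec.time_s, rec.head_velocity_dps, rec.eye_velocity_dps):
        buf.write(f"{format(t, '.9g')},{cell(h)},{cell(e)}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
    return os.fspath(path)


def _parse_header_metadata(path: str | os.PathLike) -> dict:
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def _sidecar_metadata(path: str | os.PathLike) -> dict:
    sidecar = os.fspath(path) + ".yaml"
    if os.path.exists(sidecar):
        with open(sidecar, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise FormatError(f"sidecar {sidecar} must contain a mapping")
        return {str(k): v for k, v in loaded.items()}
    return {}


def _match_columns(columns, dialect: str) -> dict:
    """Map semantic roles -> actual column names, or raise FormatError."""
    if dialect == "canonical":
        mapping = {}
        for want in _CANONICAL_COLUMNS:
            if want not in columns:
                raise FormatError(f"missing required column {want!r}")
            mapping[want] = want
        return mapping
    # otosuite_like: case-insensitive substring match, extra columns ignored
    lowered = {c.lower(): c for c in columns}
    mapping = {}
    for role, keys in (("time_s", ("time",)),
                       ("head_velocity_dps", ("head",)),
                       ("eye_velocity_dps", ("eye",))):
        hit = next((orig for low, orig in lowered.items()
                    if any(k in low for k in keys)), None)
        if hit is None:
            raise FormatError(f"no column matching {keys[0]!r} for {role}")
        mapping[role] = hit
    return mapping


def read_recording(path: str | os.PathLike, dialect: str = "canonical") -> Recording:
    """Read a recording CSV in the ``canonical`` or ``otosuite_like`` dialect.

    Rows are never dropped: velocity cells that are empty or non-numeric
    become NaN with ``missing_mask`` set.  Non-monotonic time raises
    :class:`~vogain.errors.DataError` naming the first offending data row.
    """
    if dialect not in ("canonical", "otosuite_like"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    meta = _sidecar_metadata(path)
    meta.update(_parse_header_metadata(path))

    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    cols = _match_columns(list(df.columns), dialect)
    time = pd.to_numeric(df[cols["time_s"]], errors="coerce").to_numpy(float)
    if not np.isfinite(time).all():
        bad = int(np.nonzero(~np.isfinite(time))[0][0])
        raise DataError(f"non-numeric time value at data row {bad}")
    head = pd.to_numeric(df[cols["head_velocity_dps"]], errors="coerce").to_numpy(float)
    eye = pd.to_numeric(df[cols["eye_velocity_dps"]], errors="coerce").to_numpy(float)

    if dialect == "otosuite_like" and len(time) > 1:
        # device exports commonly use milliseconds; a median step > 0.5
        # implies no plausible sample rate in seconds
        if float(np.median(np.diff(time))) > 0.5:
            time = time / 1000.0
    time = time - time[0]

    dt = np.diff(time)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        raise DataError(f"time_s not strictly increasing at data row {int(bad[0]) + 1}")

    if "sample_rate_hz" in meta:
        fs = float(meta["sample_rate_hz"])
    else:
        fs = 1.0 / float(np.median(dt))

    rec = Recording(
        participant_id=str(meta.get("participant_id", "unknown")),
        age_years=float(meta.get("age_years", 0.0)),
        test_type=str(meta.get("test_type", "VVOR")),
        intended_frequency_hz=float(meta.get("intended_frequency_hz", 1.0)),
        sample_rate_hz=fs,
        time_s=time,
        head_velocity_dps=head,
        eye_velocity_dps=eye,
        missing_mask=~(np.isfinite(head) & np.isfinite(eye)),
    )
    return rec.validate()


def slice_recording(rec: Recording, start: int, end: int) -> Recording:
    """Return the sub-recording over the half-open sample span [start, end)."""
    if not (0 <= start < end <= len(rec)):
        raise ParameterError(f"invalid slice [{start}, {end}) for length {len(rec)}")
    return replace(
        rec,
        time_s=rec.time_s[start:end] - rec.time_s[start],
        head_velocity_dps=rec.head_velocity_dps[start:end],
        eye_velocity_dps=rec.eye_velocity_dps[start:end],
        missing_mask=rec.missing_mask[start:end],
    )
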