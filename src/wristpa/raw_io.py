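"""Raw/epoch/summary file I/O and the core recording container.

On-disk formats (all plain text, gzip auto-detected by ``.gz`` extension):

* raw CSV — ``time,x,y,z[,temperature]``; ISO-8601 timestamps with UTC
  offset, acceleration in gravitational units *g*;
* epoch CSV — ``epoch_start,vm_mg,wear_flag,imputed_flag,valid_fraction``;
* participant summary — JSON with units encoded in key names (mg, hours).

Acceleration is stored in g on disk and reported in mg (1 g = 1000 mg).
Time-of-day logic elsewhere in the package uses LOCAL wall-clock time, so a
recording keeps its original UTC offset and exposes a naive local timestamp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import DataError, FormatError


@dataclass
class QualityReport:
    """Counts of data-quality events logged along the pipeline."""

    n_samples: int = 0
    clips_before_calib: int = 0
    clips_after_calib: int = 0
    interrupts: int = 0
    error_readings: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "clips_before_calib", "clips_after_calib",
                     "interrupts", "error_readings"):
            if getattr(self, name) < 0:
                raise ValueError(f"QualityReport.{name} must be >= 0")

    def to_dict(self) -> dict:
        return {
            "n_samples": int(self.n_samples),
            "clips_before_calib": int(self.clips_before_calib),
            "clips_after_calib": int(self.clips_after_calib),
            "interrupts": int(self.interrupts),
            "error_readings": int(self.error_readings),
        }


@dataclass
class RawRecording:
    """A raw triaxial recording.

    ``t`` holds seconds since the first sample (strictly increasing); the
    absolute start is ``start_time`` (timezone-aware when the source carried
    an offset).  ``xyz`` is an (n, 3) array in g, clamped to the sensor's
    dynamic range; samples that hit the range are flagged in ``clipped``.
    """

    device_id: str
    start_time: pd.Timestamp
    nominal_rate_hz: float
    t: np.ndarray
    xyz: np.ndarray
    temperature_c: Optional[np.ndarray] = None
    clipped: np.ndarray = None  # type: ignore[assignment]
    quality: QualityReport = field(default_factory=QualityReport)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be an (n, 3) array")
        if len(self.t) != len(self.xyz):
            raise ValueError("t and xyz length mismatch")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            bad = int(np.argmax(np.diff(self.t) <= 0)) + 1
            raise DataError(f"timestamps not strictly increasing at row {bad}")
        if not self.nominal_rate_hz > 0:
            raise ValueError("nominal_rate_hz must be positive")
        if self.clipped is None:
            self.clipped = np.zeros(len(self.t), dtype=bool)
        self.quality.n_samples = len(self.t)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def start_local(self) -> pd.Timestamp:
        """Naive local wall-clock start (drops the offset, keeps wall time)."""
        if self.start_time.tzinfo is not None:
            return self.start_time.tz_localize(None)
        return self.start_time

    @property
    def duration_days(self) -> float:
        if len(self.t) < 2:
            return 0.0
        return float(self.t[-1] - self.t[0]) / 86400.0

    def timestamps(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(
            np.round(self.t * 1e6).astype("int64"), unit="us")


def clamp_to_range(xyz: np.ndarray, clip_limit_g: float) -> tuple[np.ndarray, np.ndarray]:
    """Clamp values beyond the dynamic range; return (clamped, clipped_mask).

    Idempotent: samples already at exactly ±limit are NOT counted as new
    clips, so counting happens once, where the out-of-range values first
    appear.
    """
    clipped = np.any(np.abs(xyz) > clip_limit_g, axis=1)
    return np.clip(xyz, -clip_limit_g, clip_limit_g), clipped


def read_raw_csv(path, config: PipelineConfig) -> RawRecording:
    """Read a raw acceleration CSV into a :class:`RawRecording`.

    Out-of-range values are clamped to ±``clip_limit_g`` and counted in
    ``quality.clips_before_calib``; rows with unparseable/missing numeric
    values are dropped and counted as ``error_readings``.
    """
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    required = ["time", "x", "y", "z"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise DataError(f"{path}: no data rows")

    ts = pd.to_datetime(df["time"], format="ISO8601")
    xyz = df[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    bad = ~np.isfinite(xyz).all(axis=1) | ts.isna().to_numpy()
    n_bad = int(bad.sum())
    if n_bad:
        df = df.loc[~bad]
        ts = ts[~bad]
        xyz = xyz[~bad]

    tsi = pd.DatetimeIndex(ts)
    dt = ((tsi - tsi[0]).total_seconds()).to_numpy()
    if np.any(np.diff(dt) <= 0):
        row = int(np.argmax(np.diff(dt) <= 0)) + 1
        raise DataError(f"{path}: non-monotone timestamp at data row {row}")

    xyz, clip_mask = clamp_to_range(xyz, config.clip_limit_g)

    temp = None
    if "temperature" in cols:
        temp = pd.to_numeric(df["temperature"], errors="coerce").to_numpy(float)

    start = ts.iloc[0]
    if not isinstance(start, pd.Timestamp):
        start = pd.Timestamp(start)
    # nominal sampling rate: the device's own cadence, inferred from the
    # median inter-sample interval (robust to interrupts)
    rate = 1.0 / float(np.median(np.diff(dt))) if len(dt) > 1 else config.resample_rate_hz
    rec = RawRecording(
        device_id=_device_id_from_path(path),
        start_time=start,
        nominal_rate_hz=rate,
        t=dt,
        xyz=xyz,
        temperature_c=temp,
        clipped=clip_mask,
    )
    rec.quality.clips_before_calib = int(clip_mask.sum())
    rec.quality.error_readings = n_bad
    return rec


def _device_id_from_path(path) -> str:
    import os

    name = os.path.basename(str(path))
    for ext in (".gz", ".csv"):
        if name.endswith(ext):
            name = name[: -len(ext)]
    return name


def write_raw_csv(rec: RawRecording, path) -> None:
    """Write a recording back to raw CSV (timestamps at µs resolution)."""
    data = {
        "time": rec.timestamps().astype(str),
        "x": rec.xyz[:, 0],
        "y": rec.xyz[:, 1],
        "z": rec.xyz[:, 2],
    }
    if rec.temperature_c is not None:
        data["temperature"] = rec.temperature_c
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# epoch CSV

def write_epochs(series, path) -> None:
    """Write an EpochSeries to CSV; re-reading reproduces the series."""
    if len(series) == 0:
        raise ValueError("refusing to write an empty epoch series")
    df = pd.DataFrame(
        {
            "epoch_start": series.starts().astype(str),
            "vm_mg": series.vm_mg,
            "wear_flag": series.wear.astype(int),
            "imputed_flag": series.imputed.astype(int),
            "valid_fraction": series.valid_fraction,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_epochs(path):
    """Read an epoch CSV written by :func:`write_epochs`."""
    from .wear_epochs import EpochSeries

    df = pd.read_csv(path)
    need = {"epoch_start", "vm_mg", "wear_flag", "imputed_flag"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: missing epoch columns {sorted(need - set(df.columns))}")
    starts = pd.to_datetime(df["epoch_start"])
    step = np.diff(starts.to_numpy()) / np.timedelta64(1, "s")
    if len(step) and not np.allclose(step, step[0]):
        raise DataError(f"{path}: epoch starts are not equally spaced")
    epoch_s = int(step[0]) if len(step) else 5
    vf = df["valid_fraction"].to_numpy(float) if "valid_fraction" in df.columns \
        else np.ones(len(df))
    return EpochSeries(
        start=starts.iloc[0],
        epoch_s=epoch_s,
        vm_mg=df["vm_mg"].to_numpy(float),
        wear=df["wear_flag"].to_numpy(int).astype(bool),
        imputed=df["imputed_flag"].to_numpy(int).astype(bool),
        valid_fraction=vf,
    )


# ---------------------------------------------------------------------------
# summary JSON

def write_summary(summary, path) -> None:
    """Serialise a ParticipantSummary to JSON (units in key names)."""
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)


def read_summary(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
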