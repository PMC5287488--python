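"""Gravity autocalibration on stationary windows.

During rest the device measures only gravity, so every stationary 10-s window
mean should lie on the unit sphere (|a| = 1 g).  Sensor offset and gain errors
move those points off the sphere; we recover per-axis offset o and gain k such
that corrected = (raw − o)·k (plus an optional linear temperature term when a
temperature channel is present) brings them back.

A single ordinary-least-squares pass cannot fit a sphere, so the fit is
iteratively re-projected: each window mean is projected onto its nearest
unit-sphere point, per-axis OLS maps current-corrected values onto the
projections, the model composition is updated, and the loop repeats until the
coefficients move by less than ``tol`` (default 1e-9) or ``max_iter``
iterations.  This is the established autocalibration scheme for free-living
wrist accelerometry.

Devices whose stationary windows do not span ±300 mg on every axis (e.g. a
recording worn in one orientation only) cannot identify the model; their
coefficients are borrowed from the previous — or failing that, the next —
recording made with the same physical device.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import UncalibratableError
from .raw_io import RawRecording, clamp_to_range

logger = logging.getLogger(__name__)


@dataclass
class StationaryWindow:
    """One 10-s window in which all three axes were still (SD < threshold)."""

    index: int                 # window number counted from the recording start
    start: pd.Timestamp        # local (naive) wall-clock start
    mean_xyz: np.ndarray       # g
    sd_mg: np.ndarray          # mg
    n: int
    temperature_c: Optional[float] = None


@dataclass
class CalibrationModel:
    offset: np.ndarray                      # g
    gain: np.ndarray                        # dimensionless
    temp_coeff: Optional[np.ndarray] = None  # g / degC (about the mean temp)
    temp_ref_c: Optional[float] = None
    rmse_before_mg: float = float("nan")
    rmse_after_mg: float = float("nan")
    n_windows: int = 0
    source: str = "self"                    # self|borrowed_previous|borrowed_next|identity

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float)
        self.gain = np.asarray(self.gain, dtype=float)
        if self.source == "identity":
            if np.any(self.offset != 0) or np.any(self.gain != 1):
                raise ValueError("identity model must have offset=0, gain=1")
        if np.any(self.gain <= 0.5) or np.any(self.gain >= 2.0):
            raise ValueError(f"gain out of plausible range (0.5, 2): {self.gain}")

    @classmethod
    def identity(cls) -> "CalibrationModel":
        return cls(offset=np.zeros(3), gain=np.ones(3), source="identity")

    def correct(self, xyz: np.ndarray,
                temperature_c: Optional[np.ndarray] = None) -> np.ndarray:
        out = (xyz - self.offset) * self.gain
        if self.temp_coeff is not None and temperature_c is not None:
            out = out + np.outer(temperature_c - self.temp_ref_c, self.temp_coeff)
        return out

    def to_dict(self) -> dict:
        d = {
            "offset": self.offset.tolist(),
            "gain": self.gain.tolist(),
            "temp_coeff": None if self.temp_coeff is None else self.temp_coeff.tolist(),
            "temp_ref_c": self.temp_ref_c,
            "rmse_before_mg": self.rmse_before_mg,
            "rmse_after_mg": self.rmse_after_mg,
            "n_windows": self.n_windows,
            "source": self.source,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        d = dict(d)
        d.pop("fitted_at", None)
        if d.get("temp_coeff") is not None:
            d["temp_coeff"] = np.asarray(d["temp_coeff"], float)
        return cls(**d)


def find_stationary_windows(rec: RawRecording,
                            config: PipelineConfig) -> list[StationaryWindow]:
    """Scan non-overlapping windows aligned to the recording start.

    A window qualifies when it is fully covered by samples (no interrupt
    inside), and the per-axis sample SD over its non-clipped samples is below
    ``stationary_sd_threshold_mg`` on all three axes.  Clipped samples are
    excluded from the statistics (clipped rest geometry is not trustworthy).
    """
    if len(rec) == 0:
        return []
    win_s = config.stationary_window_s
    widx = np.floor(rec.t / win_s).astype(np.int64)
    nwin = int(widx[-1]) + 1
    expected = int(round(win_s * rec.nominal_rate_hz))

    counts_all = np.bincount(widx, minlength=nwin)
    ok = ~rec.clipped
    counts = np.bincount(widx[ok], minlength=nwin).astype(float)
    sums = np.empty((nwin, 3))
    sumsq = np.empty((nwin, 3))
    for a in range(3):
        v = rec.xyz[ok, a]
        sums[:, a] = np.bincount(widx[ok], weights=v, minlength=nwin)
        sumsq[:, a] = np.bincount(widx[ok], weights=v * v, minlength=nwin)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts[:, None]
        var = (sumsq - sums**2 / counts[:, None]) / (counts[:, None] - 1)
    sd_mg = np.sqrt(np.clip(var, 0, None)) * 1000.0

    covered = counts_all >= expected           # full coverage, no interrupts
    enough = counts >= max(2, 0.5 * expected)  # enough unclipped samples
    still = np.all(sd_mg < config.stationary_sd_threshold_mg, axis=1)
    usable = covered & enough & still

    temp_mean = None
    if rec.temperature_c is not None:
        temp_mean = np.bincount(widx[ok], weights=rec.temperature_c[ok],
                                minlength=nwin) / np.maximum(counts, 1)

    base = rec.start_local
    out = []
    for i in np.flatnonzero(usable):
        out.append(StationaryWindow(
            index=int(i),
            start=base + pd.Timedelta(seconds=float(i) * win_s),
            mean_xyz=mean[i].copy(),
            sd_mg=sd_mg[i].copy(),
            n=int(counts[i]),
            temperature_c=None if temp_mean is None else float(temp_mean[i]),
        ))
    return out


def window_means(windows: Sequence[StationaryWindow]) -> np.ndarray:
    return np.array([w.mean_xyz for w in windows], dtype=float).reshape(-1, 3)


def check_calibratable(windows: Sequence[StationaryWindow],
                       config: PipelineConfig) -> tuple[bool, np.ndarray, np.ndarray]:
    """True iff every axis' window means span beyond ±calib_range_mg.

    Returns (ok, per-axis min, per-axis max) in g.
    """
    if len(windows) == 0:
        return False, np.full(3, np.nan), np.full(3, np.nan)
    m = window_means(windows)
    lo, hi = m.min(axis=0), m.max(axis=0)
    r = config.calib_range_mg / 1000.0
    return bool(np.all(lo < -r) and np.all(hi > r)), lo, hi


def _sphere_rmse_mg(pts: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.linalg.norm(pts, axis=1) - 1.0) ** 2)) * 1000.0)


def fit_calibration(windows: Sequence[StationaryWindow],
                    config: PipelineConfig,
                    tol: float = 1e-9,
                    max_iter: int = 1000) -> CalibrationModel:
    """Fit offset/gain (+ optional temperature terms) by iteratively
    re-projected per-axis OLS onto the unit gravity sphere.

    Raises :class:`UncalibratableError` when fewer than ``calib_min_windows``
    windows exist or the orientation range check fails.
    """
    ok, lo, hi = check_calibratable(windows, config)
    if len(windows) < config.calib_min_windows or not ok:
        raise UncalibratableError(
            f"uncalibratable: n_windows={len(windows)}, "
            f"axis range [{np.round(lo, 3)}, {np.round(hi, 3)}] g "
            f"(need ±{config.calib_range_mg} mg on every axis)")

    M = window_means(windows)
    temps = np.array([w.temperature_c for w in windows], dtype=float) \
        if all(w.temperature_c is not None for w in windows) else None
    use_temp = temps is not None and np.ptp(temps) > 0
    tref = float(np.mean(temps)) if use_temp else None
    tau = (temps - tref) if use_temp else None

    offset = np.zeros(3)
    gain = np.ones(3)
    tcoef = np.zeros(3) if use_temp else None

    def corrected():
        c = (M - offset) * gain
        if use_temp:
            c = c + np.outer(tau, tcoef)
        return c

    prev = np.concatenate([offset, gain] + ([tcoef] if use_temp else []))
    for _ in range(max_iter):
        C = corrected()
        norms = np.linalg.norm(C, axis=1)
        target = C / norms[:, None]
        for a in range(3):
            if use_temp:
                X = np.column_stack([np.ones(len(C)), C[:, a], tau])
            else:
                X = np.column_stack([np.ones(len(C)), C[:, a]])
            coef, *_ = np.linalg.lstsq(X, target[:, a], rcond=None)
            alpha, beta = coef[0], coef[1]
            # compose: beta*((m-o)k + t*tau) + alpha + gamma*tau
            gain[a] = gain[a] * beta
            offset[a] = offset[a] - alpha / gain[a]
            if use_temp:
                tcoef[a] = tcoef[a] * beta + coef[2]
        cur = np.concatenate([offset, gain] + ([tcoef] if use_temp else []))
        if np.max(np.abs(cur - prev)) < tol:
            break
        prev = cur

    model = CalibrationModel(
        offset=offset,
        gain=gain,
        temp_coeff=tcoef if use_temp else None,
        temp_ref_c=tref,
        rmse_before_mg=_sphere_rmse_mg(M),
        rmse_after_mg=_sphere_rmse_mg(corrected()),
        n_windows=len(windows),
        source="self",
    )
    return model


def apply_calibration(rec: RawRecording, model: CalibrationModel,
                      config: Optional[PipelineConfig] = None) -> RawRecording:
    """Return a corrected copy of the recording; clips re-counted after
    correction (a corrected value can leave the dynamic range)."""
    limit = config.clip_limit_g if config is not None else 8.0
    corrected = model.correct(rec.xyz, rec.temperature_c)
    corrected, newly_clipped = clamp_to_range(corrected, clip_limit_g=limit)
    out = RawRecording(
        device_id=rec.device_id,
        start_time=rec.start_time,
        nominal_rate_hz=rec.nominal_rate_hz,
        t=rec.t,
        xyz=corrected,
        temperature_c=rec.temperature_c,
        clipped=rec.clipped | newly_clipped,
        quality=rec.quality,
    )
    out.quality.clips_after_calib = int((np.abs(corrected) >= limit).any(axis=1).sum())
    return out


# ---------------------------------------------------------------------------
# registry / coefficient borrowing

class CalibrationRegistry:
    """Chronological per-device store of fitted models (JSON on disk)."""

    def __init__(self) -> None:
        self._models: dict[str, list[tuple[pd.Timestamp, CalibrationModel]]] = {}

    def add(self, device_id: str, fitted_at: pd.Timestamp,
            model: CalibrationModel) -> None:
        lst = self._models.setdefault(device_id, [])
        lst.append((pd.Timestamp(fitted_at), model))
        lst.sort(key=lambda x: x[0])

    def previous(self, device_id: str, when: pd.Timestamp) -> Optional[CalibrationModel]:
        cands = [(ts, m) for ts, m in self._models.get(device_id, [])
                 if ts < when and m.source == "self"]
        return cands[-1][1] if cands else None

    def next(self, device_id: str, when: pd.Timestamp) -> Optional[CalibrationModel]:
        cands = [(ts, m) for ts, m in self._models.get(device_id, [])
                 if ts >= when and m.source == "self"]
        return cands[0][1] if cands else None

    def save(self, path) -> None:
        payload = {
            dev: [dict(m.to_dict(), fitted_at=str(ts)) for ts, m in lst]
            for dev, lst in self._models.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def load(cls, path) -> "CalibrationRegistry":
        reg = cls()
        with open(path) as fh:
            payload = json.load(fh)
        for dev, lst in payload.items():
            for d in lst:
                reg.add(dev, pd.Timestamp(d["fitted_at"]),
                        CalibrationModel.from_dict(d))
        return reg


def resolve_calibration(rec: RawRecording,
                        registry: Optional[CalibrationRegistry],
                        config: PipelineConfig,
                        windows: Optional[Sequence[StationaryWindow]] = None,
                        ) -> CalibrationModel:
    """Self-fit when possible; otherwise borrow from the same device's
    previous (preferred) or next recording; otherwise fall back to identity
    with a warning."""
    if windows is None:
        windows = find_stationary_windows(rec, config)
    try:
        return fit_calibration(windows, config)
    except UncalibratableError:
        pass
    when = rec.start_time
    if registry is not None:
        prev = registry.previous(rec.device_id, when)
        if prev is not None:
            m = CalibrationModel.from_dict(prev.to_dict())
            m.source = "borrowed_previous"
            return m
        nxt = registry.next(rec.device_id, when)
        if nxt is not None:
            m = CalibrationModel.from_dict(nxt.to_dict())
            m.source = "borrowed_next"
            return m
    warnings.warn(
        f"device {rec.device_id}: uncalibratable and no registry model; "
        "proceeding with identity calibration", stacklevel=2)
    logger.warning("identity calibration used for device %s", rec.device_id)
    return CalibrationModel.identity()
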