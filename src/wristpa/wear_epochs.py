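"""5-s epochs, non-wear detection, diurnal imputation, inclusion rules.

The processed activity signal (mg) is averaged into 5-s epochs aligned to the
local-midnight 5-s grid.  Non-wear is a run of consecutive stationary 10-s
windows spanning at least 60 minutes; such episodes are removed and imputed
with the mean of worn values at the same minute of day on the other measured
days (a diurnal-bias-free fill-in: if a device is systematically off at
night, the crude worn mean overestimates true activity).  Participants with
under 72 h of wear, or without worn data in every one-hour bin of the 24-h
cycle, are excluded from outcome analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig, samples_per_epoch
from .calibration import StationaryWindow
from .signal_chain import UniformSignal

MINUTES_PER_DAY = 1440


@dataclass
class EpochSeries:
    """Contiguous 5-s epochs on the local wall-clock grid.

    ``start`` is the (naive local) timestamp of the first epoch; epoch *i*
    covers [start + i·epoch_s, start + (i+1)·epoch_s).  ``wear`` and
    ``imputed`` are mutually exclusive; ``fallback_imputed`` marks epochs
    whose imputation needed the widened ±30-min pool or the overall mean.
    """

    start: pd.Timestamp
    epoch_s: int
    vm_mg: np.ndarray
    wear: np.ndarray
    imputed: np.ndarray
    valid_fraction: np.ndarray
    fallback_imputed: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        if self.start.tzinfo is not None:
            self.start = self.start.tz_localize(None)
        self.vm_mg = np.asarray(self.vm_mg, dtype=float)
        self.wear = np.asarray(self.wear, dtype=bool)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        self.valid_fraction = np.asarray(self.valid_fraction, dtype=float)
        if self.fallback_imputed is None:
            self.fallback_imputed = np.zeros(len(self.vm_mg), dtype=bool)
        n = len(self.vm_mg)
        if not (len(self.wear) == len(self.imputed) == len(self.valid_fraction) == n):
            raise ValueError("epoch arrays must have equal length")
        if np.any(self.wear & self.imputed):
            raise ValueError("an epoch cannot be both worn and imputed")
        sec = (self.start - self.start.normalize()).total_seconds()
        if sec % self.epoch_s != 0:
            raise ValueError("epoch grid must align to local midnight")

    def __len__(self) -> int:
        return len(self.vm_mg)

    def starts(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(len(self)) * self.epoch_s, unit="s")

    # -- wall-clock index helpers (all derived arithmetically from `start`) --
    def _sec_of_day0(self) -> float:
        return float((self.start - self.start.normalize()).total_seconds())

    def second_of_day(self) -> np.ndarray:
        s = self._sec_of_day0() + np.arange(len(self), dtype=np.int64) * self.epoch_s
        return s % 86400

    def minute_of_day(self) -> np.ndarray:
        return (self.second_of_day() // 60).astype(np.int64)

    def hour_of_day(self) -> np.ndarray:
        return (self.second_of_day() // 3600).astype(np.int64)

    def day_index(self) -> np.ndarray:
        s = self._sec_of_day0() + np.arange(len(self), dtype=np.int64) * self.epoch_s
        return (s // 86400).astype(np.int64)

    def copy(self) -> "EpochSeries":
        return EpochSeries(
            start=self.start, epoch_s=self.epoch_s,
            vm_mg=self.vm_mg.copy(), wear=self.wear.copy(),
            imputed=self.imputed.copy(),
            valid_fraction=self.valid_fraction.copy(),
            fallback_imputed=self.fallback_imputed.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch_start": self.starts(),
            "vm_mg": self.vm_mg,
            "wear": self.wear,
            "imputed": self.imputed,
            "valid_fraction": self.valid_fraction,
        })


@dataclass
class NonWearEpisode:
    """Half-open [start, end) local-time interval of presumed device-off."""

    start: pd.Timestamp
    end: pd.Timestamp

    @property
    def duration_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


@dataclass
class IntensityECDF:
    """Cumulative hours spent at or below each intensity breakpoint."""

    grid_mg: np.ndarray
    cum_time_h: np.ndarray


@dataclass
class InclusionResult:
    included: bool
    wear_hours: float
    covered_hour_bins: int
    reason: str = ""


def make_epochs(activity: UniformSignal, config: PipelineConfig) -> EpochSeries:
    """Average the scalar mg signal into 5-s epochs on the local 5-s grid.

    Partial first/last epochs are dropped.  Epoch value is the mean of
    non-missing samples; ``valid_fraction`` records coverage; fully missing
    epochs get NaN and are non-wear candidates.
    """
    spe = int(round(config.epoch_s * activity.rate_hz))
    if abs(spe - config.epoch_s * activity.rate_hz) > 1e-9:
        raise ValueError("epoch_s * rate must be integral")
    ls = activity.start_local
    sec0 = (ls - ls.normalize()).total_seconds()
    abs_sec = sec0 + np.arange(len(activity)) / activity.rate_hz
    eidx = np.floor(abs_sec / config.epoch_s).astype(np.int64)
    eidx -= eidx[0]
    nep = int(eidx[-1]) + 1

    counts_all = np.bincount(eidx, minlength=nep)
    ok = ~activity.missing
    vals = np.where(ok, np.nan_to_num(activity.values), 0.0)
    counts = np.bincount(eidx[ok], minlength=nep).astype(float)
    sums = np.bincount(eidx, weights=vals, minlength=nep)
    with np.errstate(invalid="ignore", divide="ignore"):
        vm = sums / counts
    vf = counts / spe

    # drop partial boundary epochs (grid coverage, not wear, decides this)
    keep = slice(None)
    lo = 1 if counts_all[0] < spe else 0
    hi = nep - 1 if counts_all[-1] < spe else nep
    keep = slice(lo, hi)
    vm, vf = vm[keep], vf[keep]

    first_epoch_sec = (np.floor(abs_sec[0] / config.epoch_s) + lo) * config.epoch_s
    start = ls.normalize() + pd.Timedelta(seconds=float(first_epoch_sec))
    n = len(vm)
    return EpochSeries(
        start=start, epoch_s=config.epoch_s,
        vm_mg=vm,
        wear=vf > 0,
        imputed=np.zeros(n, dtype=bool),
        valid_fraction=np.clip(vf, 0.0, 1.0),
    )


def detect_nonwear(windows: Sequence[StationaryWindow],
                   config: PipelineConfig) -> list[NonWearEpisode]:
    """Maximal runs of consecutive (gap-free) stationary windows spanning at
    least ``nonwear_min_minutes`` become non-wear episodes."""
    if not windows:
        return []
    win_s = config.stationary_window_s
    need = int(np.ceil(config.nonwear_min_minutes * 60.0 / win_s))
    idx = np.array([w.index for w in windows])
    episodes: list[NonWearEpisode] = []
    run_start = 0
    for i in range(1, len(idx) + 1):
        if i == len(idx) or idx[i] != idx[i - 1] + 1:
            if i - run_start >= need:
                episodes.append(NonWearEpisode(
                    start=windows[run_start].start,
                    end=windows[i - 1].start + pd.Timedelta(seconds=win_s),
                ))
            run_start = i
    return episodes


def flag_wear(epochs: EpochSeries,
              episodes: Sequence[NonWearEpisode]) -> EpochSeries:
    """Epochs overlapping any episode -> wear=False; all other epochs with
    any valid samples -> wear=True."""
    out = epochs.copy()
    out.wear = out.valid_fraction > 0
    e = out.epoch_s
    for ep in episodes:
        a = (ep.start - out.start).total_seconds()
        b = (ep.end - out.start).total_seconds()
        lo = max(0, int(np.floor(a / e - 1)) + 1)      # first i with i*e + e > a
        hi = min(len(out), int(np.ceil(b / e)))        # first i with i*e >= b
        if lo < hi:
            out.wear[lo:hi] = False
    out.imputed[:] = False
    return out


def _circular_window_sum(arr: np.ndarray, half: int) -> np.ndarray:
    """Sum over a centred window of +-half entries with wrap-around.
    Works on 1-D (length L) or 2-D (L, D) arrays along axis 0."""
    L = arr.shape[0]
    ext = np.concatenate([arr[-half:], arr, arr[: half + 1]], axis=0)
    cs = np.cumsum(ext, axis=0)
    zero = np.zeros((1,) + arr.shape[1:], dtype=cs.dtype)
    cs = np.concatenate([zero, cs], axis=0)
    return cs[2 * half + 1:2 * half + 1 + L] - cs[0:L]


def impute_nonwear(epochs: EpochSeries, config: PipelineConfig) -> EpochSeries:
    """Fill non-wear/missing epochs with the mean worn value at the same
    minute of day on the other days.

    Fallbacks when the same-minute pool is empty: widen to ±30 min (other
    days), then the participant's overall worn mean; both are flagged in
    ``fallback_imputed``.  Worn epochs are never touched.
    """
    out = epochs.copy()
    worn = out.wear
    need = ~worn
    if not need.any():
        return out
    if not worn.any():
        # nothing to impute from: leave unimputable epochs as-is
        return out

    m = out.minute_of_day()
    d = out.day_index()
    D = int(d.max()) + 1
    key = m * D + d

    vm_w = np.where(worn, out.vm_mg, 0.0)
    S = np.bincount(m[worn], weights=out.vm_mg[worn], minlength=MINUTES_PER_DAY)
    C = np.bincount(m[worn], minlength=MINUTES_PER_DAY).astype(float)
    Sd = np.bincount(key[worn], weights=out.vm_mg[worn],
                     minlength=MINUTES_PER_DAY * D).reshape(MINUTES_PER_DAY, D)
    Cd = np.bincount(key[worn], minlength=MINUTES_PER_DAY * D
                     ).reshape(MINUTES_PER_DAY, D).astype(float)

    mi, di = m[need], d[need]
    cnt1 = C[mi] - Cd[mi, di]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean1 = (S[mi] - Sd[mi, di]) / cnt1

    half = config.impute_fallback_window_min
    Sw = _circular_window_sum(S, half)
    Cw = _circular_window_sum(C, half)
    Sdw = _circular_window_sum(Sd, half)
    Cdw = _circular_window_sum(Cd, half)
    cnt2 = Cw[mi] - Cdw[mi, di]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean2 = (Sw[mi] - Sdw[mi, di]) / cnt2

    overall = S.sum() / C.sum()
    filled = np.where(cnt1 > 0, mean1, np.where(cnt2 > 0, mean2, overall))
    fb = cnt1 <= 0

    out.vm_mg[need] = filled
    out.imputed[need] = True
    out.fallback_imputed[need] = fb
    return out


def intensity_ecdf(epochs: EpochSeries, config: PipelineConfig) -> IntensityECDF:
    """Cumulative time (hours) at or below each breakpoint, over worn and
    imputed epochs.  Values above the top breakpoint count in the final bin
    so the curve saturates at the total measured+imputed time."""
    grid = np.arange(0.0, config.ecdf_max_mg + config.ecdf_step_mg / 2,
                     config.ecdf_step_mg)
    mask = epochs.wear | epochs.imputed
    vm = np.minimum(epochs.vm_mg[mask], grid[-1])
    vm = np.sort(vm)
    counts = np.searchsorted(vm, grid, side="right")
    cum_h = counts * epochs.epoch_s / 3600.0
    return IntensityECDF(grid_mg=grid, cum_time_h=cum_h)


def overall_outcome(epochs: EpochSeries) -> float:
    """Mean vm (mg) over all worn and imputed epochs — the primary activity
    outcome."""
    mask = epochs.wear | epochs.imputed
    if not mask.any():
        raise ValueError("no worn or imputed epochs to average")
    return float(np.mean(epochs.vm_mg[mask]))


def check_inclusion(epochs: EpochSeries, config: PipelineConfig) -> InclusionResult:
    """>=72 h of wear and worn data in every hour-of-day bin (pre-imputation)."""
    worn = epochs.wear
    wear_hours = float(worn.sum()) * epochs.epoch_s / 3600.0
    bins = int(len(np.unique(epochs.hour_of_day()[worn])))
    reasons = []
    if wear_hours < config.min_wear_h:
        reasons.append(f"<{config.min_wear_h:g}h wear ({wear_hours:.2f}h)")
    if bins < config.hourly_coverage_bins:
        reasons.append(f"hour-of-day coverage {bins}/{config.hourly_coverage_bins} bins")
    return InclusionResult(
        included=not reasons,
        wear_hours=wear_hours,
        covered_hour_bins=bins,
        reason="; ".join(reasons),
    )
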