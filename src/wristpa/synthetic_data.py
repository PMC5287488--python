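"""Synthetic raw recordings and cohorts with known ground truth.

Access to the real cohort's raw data is controlled, so every processing stage
is validated against simulated wrist recordings instead.  A simulated
participant alternates rest bouts (a random fixed orientation on the unit
gravity sphere plus sensor noise — these are the stationary windows the
calibration and non-wear logic feed on) with activity bouts (a slow
orientation random walk plus a rectified band-limited activity component
riding along the orientation, scaled so each wall-clock hour's mean truncated
ENMO hits that hour's diurnal target exactly).  On top of the clean trace the
generator embeds, and records as ground truth:

* miscalibration — the inverse model ``stored = clean/gain + offset``;
* non-wear episodes — still periods, new orientation, low noise;
* interrupts — deleted sample runs;
* clips — samples pushed beyond the ±8 g dynamic range.

The default diurnal profile follows the published hour-of-day activity shape
(night ≈ 3–4 mg, morning rise, afternoon peak ≈ 45 mg, evening decline), with
six-hour-quadrant means of 4.4 / 38.6 / 44.3 / 26.4 mg and an overall mean of
≈ 28.4 mg.  Cohort generation draws per-participant overall levels from
age-band-specific normals (31 / 29 / 26.5 / 23.5 mg, SD 8 mg).

An epoch-level generator (``simulate_epoch_series``) is also provided for
cohort-scale tests of the imputation and reliability machinery, where
synthesising the raw 100 Hz signal for hundreds of participants would be
pointless: it emits worn 5-s epochs directly, with between-participant level
variance, day-to-day multipliers, and within-day epoch noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .calibration import StationaryWindow
from .raw_io import QualityReport, RawRecording, clamp_to_range
from .wear_epochs import EpochSeries

DEFAULT_START = "2014-05-12T10:00:00+01:00"

#: per-age-band mean overall activity (mg) and common SD, echoing the
#: published cohort gradient
STRATUM_MEANS_MG = {"45-54": 31.0, "55-64": 29.0, "65-74": 26.5, "75-79": 23.5}
STRATUM_SD_MG = 8.0


def default_diurnal_profile() -> np.ndarray:
    """Hour-of-day target mean truncated ENMO (mg), 24 values.

    Quadrant means 4.4 / 38.6 / 44.3 / 26.4 mg; overall mean ≈ 28.4 mg.
    """
    return np.array([
        3.6, 3.1, 2.9, 3.1, 4.2, 9.5,          # 00-05
        21.0, 33.0, 41.0, 44.6, 46.0, 46.0,    # 06-11
        45.8, 45.0, 44.5, 44.0, 43.5, 43.0,    # 12-17
        41.0, 36.0, 30.0, 23.0, 17.0, 11.4,    # 18-23
    ])


@dataclass
class SimScenario:
    """All knobs of one simulated participant recording."""

    seed: int = 0
    days: float = 7.0
    rate_hz: float = 100.0
    start_time: str = DEFAULT_START
    diurnal_profile: np.ndarray = dc_field(default_factory=default_diurnal_profile)
    rest_fraction: float = 0.5
    offset_mg: tuple = (0.0, 0.0, 0.0)
    gain: tuple = (1.0, 1.0, 1.0)
    noise_sd_mg: float = 5.0
    nonwear_noise_sd_mg: float = 3.0
    nonwear_intervals: list = dc_field(default_factory=list)   # (start_s, end_s)
    interrupt_intervals: list = dc_field(default_factory=list)  # (start_s, end_s)
    clip_rate: float = 0.0
    activity_band_hz: tuple = (0.5, 10.0)
    bout_minutes: tuple = (4.0, 12.0)
    orientation_step: float = 0.25       # random-walk step per keyframe (10 s)

    def __post_init__(self) -> None:
        self.diurnal_profile = np.asarray(self.diurnal_profile, dtype=float)
        if self.diurnal_profile.shape != (24,):
            raise ValueError("diurnal_profile must have 24 entries")
        if np.any(self.diurnal_profile < 0):
            raise ValueError("diurnal_profile values must be >= 0")
        if not 0 <= self.rest_fraction <= 1:
            raise ValueError("rest_fraction must be in [0, 1]")
        if self.activity_band_hz[1] >= self.rate_hz / 2:
            raise ValueError("activity band must lie below the Nyquist rate")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline should recover."""

    true_offset_g: np.ndarray
    true_gain: np.ndarray
    true_nonwear: list           # list of (start, end) local naive Timestamps
    true_overall_mean_mg: float
    true_hourly_mean_mg: np.ndarray


def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _bout_schedule(rng: np.random.Generator, total_s: float,
                   rest_fraction: float, bout_minutes: tuple) -> list:
    """Alternating (is_rest, start_s, end_s) bouts covering [0, total_s)."""
    bouts = []
    t = 0.0
    is_rest = bool(rng.integers(0, 2))
    lo, hi = bout_minutes
    while t < total_s:
        frac = rest_fraction if is_rest else (1.0 - rest_fraction)
        if frac <= 1e-9:          # degenerate: this bout type never occurs
            is_rest = not is_rest
            continue
        dur = rng.uniform(lo, hi) * 60.0 * 2.0 * frac
        end = min(t + dur, total_s)
        bouts.append((is_rest, t, end))
        t = end
        is_rest = not is_rest
    return bouts


def simulate_participant(scenario: SimScenario) -> tuple[RawRecording, GroundTruth]:
    """Generate one raw recording plus its ground truth.

    Ground-truth activity means describe the wear behaviour *before* non-wear
    replacement — exactly what non-wear removal plus diurnal imputation is
    supposed to recover.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    rate = sc.rate_hz
    n = int(round(sc.days * 86400 * rate))
    if n < rate * 60:
        raise ValueError("scenario too short to be meaningful (< 1 min)")
    t = np.arange(n) / rate
    start = pd.Timestamp(sc.start_time)
    start_local = start.tz_localize(None) if start.tzinfo is not None else start
    sec_of_day0 = (start_local - start_local.normalize()).total_seconds()

    # --- bout schedule and active mask -----------------------------------
    total_s = n / rate
    bouts = _bout_schedule(rng, total_s, sc.rest_fraction, sc.bout_minutes)
    active = np.zeros(n, dtype=bool)
    for is_rest, a, b in bouts:
        if not is_rest:
            active[int(a * rate):int(np.ceil(b * rate))] = True

    # --- orientation: keyframes every 10 s -------------------------------
    key_s = 10.0
    nk = int(np.ceil(total_s / key_s)) + 1
    kt = np.arange(nk) * key_s
    u = np.empty((nk, 3))
    u[0] = _random_unit(rng)[0]
    key_active = active[np.minimum((kt * rate).astype(int), n - 1)]
    # rest bouts hold a fixed orientation; a new one is drawn whenever rest
    # follows activity (the wearer settles in a new pose), so calibration
    # sees many sphere points; back-to-back rest keeps its orientation
    rest_starts = set()
    prev_rest = True
    for is_rest, a, b in bouts:
        if is_rest and not prev_rest:
            rest_starts.add(int(a // key_s))
        prev_rest = is_rest
    for k in range(1, nk):
        if k in rest_starts:
            u[k] = _random_unit(rng)[0]
        elif key_active[k]:
            step = u[k - 1] + sc.orientation_step * rng.standard_normal(3)
            u[k] = step / np.linalg.norm(step)
        else:
            u[k] = u[k - 1]
    orient = np.empty((n, 3))
    for a in range(3):
        orient[:, a] = np.interp(t, kt, u[:, a])
    orient /= np.linalg.norm(orient, axis=1, keepdims=True)

    # --- activity amplitude, normalised per wall-clock hour --------------
    sos = sps.butter(4, sc.activity_band_hz, btype="band", fs=rate, output="sos")
    b = sps.sosfiltfilt(sos, rng.standard_normal(n))
    amp = np.abs(b) * active

    hour_abs = ((sec_of_day0 + t) // 3600).astype(np.int64)
    hour_abs -= hour_abs[0]
    nhours = int(hour_abs[-1]) + 1
    # hour-of-day label for each absolute hour slice of the recording
    first_hour_of_day = int((sec_of_day0 // 3600) % 24)
    hod = (first_hour_of_day + np.arange(nhours)) % 24

    counts = np.bincount(hour_abs, minlength=nhours).astype(float)
    sums = np.bincount(hour_abs, weights=amp, minlength=nhours)
    target_g = sc.diurnal_profile[hod] / 1000.0
    scale = np.zeros(nhours)
    feasible = sums > 0
    infeasible = (~feasible) & (target_g > 0) & (counts > 0)
    if np.any(infeasible):
        raise ValueError(
            "infeasible diurnal target: hour(s) with a positive target but "
            "no active samples (rest_fraction too high?)")
    scale[feasible] = target_g[feasible] * counts[feasible] / sums[feasible]
    a_g = amp * scale[hour_abs]     # clean truncated-ENMO series, in g

    true_hourly = np.zeros(24)
    hod_per_sample = hod[hour_abs]
    for h in range(24):
        m = hod_per_sample == h
        true_hourly[h] = a_g[m].mean() * 1000.0 if m.any() else np.nan
    true_overall = float(a_g.mean() * 1000.0)

    # --- non-wear: still, new orientation, low noise ----------------------
    noise_sd = np.full(n, sc.noise_sd_mg / 1000.0)
    nonwear_ts = []
    for a0, b0 in sc.nonwear_intervals:
        i0, i1 = int(a0 * rate), min(int(b0 * rate), n)
        a_g[i0:i1] = 0.0
        orient[i0:i1] = _random_unit(rng)[0]
        noise_sd[i0:i1] = sc.nonwear_noise_sd_mg / 1000.0
        nonwear_ts.append((start_local + pd.Timedelta(seconds=a0),
                           start_local + pd.Timedelta(seconds=b0)))

    v = orient * (1.0 + a_g)[:, None] + noise_sd[:, None] * rng.standard_normal((n, 3))

    # --- embed miscalibration (inverse model) -----------------------------
    gain = np.asarray(sc.gain, float)
    offset = np.asarray(sc.offset_mg, float) / 1000.0
    stored = v / gain + offset

    # --- clips -------------------------------------------------------------
    if sc.clip_rate > 0:
        k = rng.binomial(n, sc.clip_rate)
        idx = rng.choice(n, size=k, replace=False)
        ax = rng.integers(0, 3, size=k)
        stored[idx, ax] = np.sign(stored[idx, ax] + 1e-12) * 8.8

    # --- interrupts: delete samples ---------------------------------------
    keep = np.ones(n, dtype=bool)
    for a0, b0 in sc.interrupt_intervals:
        keep[int(a0 * rate):int(b0 * rate)] = False
    t_out, stored = t[keep], stored[keep]

    stored, clip_mask = clamp_to_range(stored, 8.0)
    rec = RawRecording(
        device_id=f"simdev{sc.seed:05d}",
        start_time=start,
        nominal_rate_hz=rate,
        t=t_out,
        xyz=stored,
        clipped=clip_mask,
        quality=QualityReport(clips_before_calib=int(clip_mask.sum())),
    )
    truth = GroundTruth(
        true_offset_g=offset,
        true_gain=gain,
        true_nonwear=nonwear_ts,
        true_overall_mean_mg=true_overall,
        true_hourly_mean_mg=true_hourly,
    )
    return rec, truth


def simulate_calibration_windows(n_windows: int,
                                 offset_mg: Sequence[float],
                                 gain: Sequence[float],
                                 noise_sd_mg: float,
                                 seed: int,
                                 temperatures_c: Optional[np.ndarray] = None,
                                 temp_coeff_g_per_c: Optional[Sequence[float]] = None,
                                 ) -> list[StationaryWindow]:
    """Stationary-window means drawn uniformly on the unit sphere, passed
    through the inverse calibration model plus noise — a direct fixture for
    the sphere fit."""
    rng = np.random.default_rng(seed)
    u = _random_unit(rng, n_windows)
    offset = np.asarray(offset_mg, float) / 1000.0
    gain = np.asarray(gain, float)
    noisy = u + rng.standard_normal((n_windows, 3)) * noise_sd_mg / 1000.0
    m = noisy / gain + offset
    if temperatures_c is not None and temp_coeff_g_per_c is not None:
        tau = temperatures_c - np.mean(temperatures_c)
        m = m - np.outer(tau, np.asarray(temp_coeff_g_per_c, float)) / gain
    base = pd.Timestamp("2014-05-12T10:00:00")
    return [
        StationaryWindow(
            index=i, start=base + pd.Timedelta(seconds=10.0 * i),
            mean_xyz=m[i],
            sd_mg=np.full(3, noise_sd_mg),
            n=1000,
            temperature_c=None if temperatures_c is None else float(temperatures_c[i]),
        )
        for i in range(n_windows)
    ]


def simulate_cohort(n: int, seed: int,
                    days: float = 7.0, rate_hz: float = 100.0,
                    **scenario_kw):
    """Raw-signal cohort with age/sex strata (generator, one participant at a
    time — recordings are large).

    Yields (RawRecording, GroundTruth, meta) where meta carries
    participant_id, sex, age, age_band and the drawn target overall level.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    base = default_diurnal_profile()
    for i in range(n):
        sex = "F" if rng.random() < 0.5 else "M"
        age = float(rng.integers(45, 80))
        band = next(b for b in STRATUM_MEANS_MG
                    if int(b.split("-")[0]) <= age <= int(b.split("-")[1]))
        level = max(5.0, rng.normal(STRATUM_MEANS_MG[band], STRATUM_SD_MG))
        profile = base * (level / base.mean())
        sc = SimScenario(
            seed=int(rng.integers(0, 2**31 - 1)),
            days=days, rate_hz=rate_hz,
            diurnal_profile=profile,
            **scenario_kw,
        )
        rec, truth = simulate_participant(sc)
        meta = {"participant_id": f"sim{seed:04d}_{i:04d}", "sex": sex,
                "age": age, "age_band": band, "target_overall_mg": level}
        yield rec, truth, meta


# ---------------------------------------------------------------------------
# epoch-level cohort (fast path for imputation / reliability machinery)

def simulate_epoch_series(seed: int,
                          days: int = 7,
                          level_mg: float = 28.4,
                          day_sd_log: float = 0.15,
                          epoch_noise_shape: float = 1.0,
                          profile: Optional[np.ndarray] = None,
                          start: str = "2014-05-12T00:00:00",
                          epoch_s: int = 5) -> tuple[EpochSeries, float]:
    """Worn 5-s epochs straight from the diurnal model.

    vm = level · shape[hour] · day_mult[day] · eps, with lognormal day
    multipliers (day-to-day behavioural variation) and unit-mean gamma epoch
    noise.  Returns (series, true_mean) where true_mean is the mean of the
    generated epochs — the 7-day quantity that truncated-wear outcomes are
    compared against.
    """
    rng = np.random.default_rng(seed)
    prof = default_diurnal_profile() if profile is None else np.asarray(profile, float)
    shape = prof / prof.mean()
    per_day = 86400 // epoch_s
    n = days * per_day
    hour = (np.arange(n) * epoch_s // 3600) % 24
    day = np.arange(n) * epoch_s // 86400
    day_mult = np.exp(rng.normal(0.0, day_sd_log, size=days)
                      - 0.5 * day_sd_log**2)
    eps = rng.gamma(epoch_noise_shape, 1.0 / epoch_noise_shape, size=n)
    vm = level_mg * shape[hour] * day_mult[day] * eps
    es = EpochSeries(
        start=pd.Timestamp(start),
        epoch_s=epoch_s,
        vm_mg=vm,
        wear=np.ones(n, dtype=bool),
        imputed=np.zeros(n, dtype=bool),
        valid_fraction=np.ones(n),
    )
    return es, float(vm.mean())


def simulate_epoch_cohort(n: int, seed: int, days: int = 7,
                          level_mean_mg: float = 28.4,
                          level_sd_mg: float = 8.0,
                          **kw) -> tuple[list[EpochSeries], np.ndarray]:
    """Cohort of fully-worn epoch series with between-person level variance."""
    rng = np.random.default_rng(seed)
    series, truths = [], []
    for i in range(n):
        level = max(3.0, rng.normal(level_mean_mg, level_sd_mg))
        es, tm = simulate_epoch_series(
            seed=int(rng.integers(0, 2**31 - 1)), days=days,
            level_mg=level, **kw)
        series.append(es)
        truths.append(tm)
    return series, np.asarray(truths)
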