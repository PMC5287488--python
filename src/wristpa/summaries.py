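"""Participant- and cohort-level descriptive outputs.

Covers the overall mean vector magnitude (mg), diurnal profiles (hourly and
six-hour quadrants), weekday/weekend and seasonal splits, wear-time
compliance, Cohen's d effect sizes, and the minimum-wear-time reliability
simulation: for fully compliant participants, random contiguous sub-windows
of 24–168 h are kept, the outcome is recomputed with imputation, and the
intraclass correlation between truncated and full 7-day outcomes measures how
much wear time a reliable measurement needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .raw_io import QualityReport
from .wear_epochs import (EpochSeries, InclusionResult, IntensityECDF,
                          check_inclusion, impute_nonwear, overall_outcome)

AGE_BANDS = ("45-54", "55-64", "65-74", "75-79")
SEASONS = ("Spring", "Summer", "Autumn", "Winter")
DEFAULT_HOURS_GRID = (24, 48, 72, 96, 120, 144, 168)


def season_of(date: pd.Timestamp) -> str:
    """Meteorological season, Spring starting on 1 March."""
    m = pd.Timestamp(date).month
    if 3 <= m <= 5:
        return "Spring"
    if 6 <= m <= 8:
        return "Summer"
    if 9 <= m <= 11:
        return "Autumn"
    return "Winter"


def age_band(age: float) -> Optional[str]:
    for band in AGE_BANDS:
        lo, hi = (int(x) for x in band.split("-"))
        if lo <= age <= hi:
            return band
    return None


@dataclass
class ParticipantSummary:
    participant_id: str
    overall_mean_mg: float
    wear_hours: float
    hourly_mean_mg: np.ndarray          # 24-vector
    quadrant_mean_mg: np.ndarray        # 00-05:59, 06-11:59, 12-17:59, 18-23:59
    weekday_mean_mg: float
    weekend_mean_mg: float
    season: str
    included: bool
    reason: str = ""
    quality: Optional[QualityReport] = None
    ecdf: Optional[IntensityECDF] = None

    def to_dict(self) -> dict:
        d = {
            "participant_id": self.participant_id,
            "overall_mean_mg": self.overall_mean_mg,
            "wear_hours": self.wear_hours,
            "hourly_mean_mg": np.asarray(self.hourly_mean_mg, float).tolist(),
            "quadrant_mean_mg": np.asarray(self.quadrant_mean_mg, float).tolist(),
            "weekday_mean_mg": self.weekday_mean_mg,
            "weekend_mean_mg": self.weekend_mean_mg,
            "season": self.season,
            "included": bool(self.included),
            "reason": self.reason,
        }
        if self.quality is not None:
            d["quality"] = self.quality.to_dict()
        if self.ecdf is not None:
            d["ecdf_grid_mg"] = self.ecdf.grid_mg.tolist()
            d["ecdf_cum_time_h"] = self.ecdf.cum_time_h.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParticipantSummary":
        ecdf = None
        if "ecdf_grid_mg" in d:
            ecdf = IntensityECDF(np.asarray(d["ecdf_grid_mg"], float),
                                 np.asarray(d["ecdf_cum_time_h"], float))
        quality = QualityReport(**d["quality"]) if "quality" in d else None
        return cls(
            participant_id=d["participant_id"],
            overall_mean_mg=d["overall_mean_mg"],
            wear_hours=d["wear_hours"],
            hourly_mean_mg=np.asarray(d["hourly_mean_mg"], float),
            quadrant_mean_mg=np.asarray(d["quadrant_mean_mg"], float),
            weekday_mean_mg=d["weekday_mean_mg"],
            weekend_mean_mg=d["weekend_mean_mg"],
            season=d["season"],
            included=d["included"],
            reason=d.get("reason", ""),
            quality=quality,
            ecdf=ecdf,
        )


def summarize_participant(epochs: EpochSeries,
                          participant_id: str,
                          config: PipelineConfig,
                          quality: Optional[QualityReport] = None,
                          ecdf: Optional[IntensityECDF] = None,
                          inclusion: Optional[InclusionResult] = None,
                          ) -> ParticipantSummary:
    """Profile fields over worn+imputed epochs; wear hours from worn only;
    season from the first worn day."""
    if inclusion is None:
        inclusion = check_inclusion(epochs, config)
    mask = epochs.wear | epochs.imputed
    vm = epochs.vm_mg
    hours = epochs.hour_of_day()

    hourly = np.full(24, np.nan)
    for h in range(24):
        sel = mask & (hours == h)
        if sel.any():
            hourly[h] = vm[sel].mean()
    quad = np.full(4, np.nan)
    for q in range(4):
        sel = mask & (hours // 6 == q)
        if sel.any():
            quad[q] = vm[sel].mean()

    dow = ((epochs.day_index() + epochs.start.normalize().dayofweek) % 7)
    wk = mask & (dow < 5)
    we = mask & (dow >= 5)
    weekday = float(vm[wk].mean()) if wk.any() else float("nan")
    weekend = float(vm[we].mean()) if we.any() else float("nan")

    worn_idx = np.flatnonzero(epochs.wear)
    if len(worn_idx):
        first_worn = epochs.start + pd.Timedelta(
            seconds=int(worn_idx[0]) * epochs.epoch_s)
    else:
        first_worn = epochs.start
    overall = float(vm[mask].mean()) if mask.any() else float("nan")

    return ParticipantSummary(
        participant_id=participant_id,
        overall_mean_mg=overall,
        wear_hours=inclusion.wear_hours,
        hourly_mean_mg=hourly,
        quadrant_mean_mg=quad,
        weekday_mean_mg=weekday,
        weekend_mean_mg=weekend,
        season=season_of(first_worn),
        included=inclusion.included,
        reason=inclusion.reason,
        quality=quality,
        ecdf=ecdf,
    )


def cohens_d(mean1: float, sd1: float, n1: int,
             mean2: float, sd2: float, n2: int) -> float:
    """Standardised mean difference with the pooled standard deviation.

    d = (m1 − m2) / sqrt(((n1−1)·sd1² + (n2−1)·sd2²) / (n1+n2−2))
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("pooled standard deviation is zero")
    return float((mean1 - mean2) / pooled)


@dataclass
class CohortTable:
    strata: pd.DataFrame               # one row per sex x age-band
    effect_sizes: dict = field(default_factory=dict)


def cohort_table(summaries: Sequence[ParticipantSummary],
                 demographics: pd.DataFrame) -> CohortTable:
    """Sex × age-band medians/IQRs for wear time and mean±SD for VM, with
    sex-within-band and adjacent-age-band Cohen's d effect sizes.

    ``demographics`` needs columns participant_id, sex, age.
    """
    demo = demographics.set_index("participant_id")
    rows = []
    for s in summaries:
        if not s.included:
            continue
        if s.participant_id not in demo.index:
            continue
        meta = demo.loc[s.participant_id]
        band = age_band(float(meta["age"]))
        if band is None:
            continue
        rows.append({"sex": str(meta["sex"]), "band": band,
                     "wear_h": s.wear_hours, "vm": s.overall_mean_mg})
    df = pd.DataFrame(rows, columns=["sex", "band", "wear_h", "vm"])

    recs = []
    for sex in sorted(df["sex"].unique()) if len(df) else []:
        for band in AGE_BANDS:
            sub = df[(df.sex == sex) & (df.band == band)]
            n = len(sub)
            recs.append({
                "sex": sex, "age_band": band, "n": n,
                "wear_median_h": sub.wear_h.median() if n else np.nan,
                "wear_q1_h": sub.wear_h.quantile(0.25) if n else np.nan,
                "wear_q3_h": sub.wear_h.quantile(0.75) if n else np.nan,
                "vm_mean_mg": sub.vm.mean() if n else np.nan,
                "vm_sd_mg": sub.vm.std(ddof=1) if n >= 2 else np.nan,
            })
    table = pd.DataFrame(recs)

    effects: dict[str, float] = {}
    def stats(sex, band):
        row = table[(table.sex == sex) & (table.age_band == band)]
        if len(row) != 1:
            return None
        r = row.iloc[0]
        if r["n"] < 2 or not np.isfinite(r["vm_sd_mg"]) or r["vm_sd_mg"] == 0:
            return None
        return r["vm_mean_mg"], r["vm_sd_mg"], int(r["n"])

    sexes = sorted(df["sex"].unique()) if len(df) else []
    if len(sexes) == 2:
        a, b = sexes
        for band in AGE_BANDS:
            sa, sb = stats(a, band), stats(b, band)
            if sa and sb:
                effects[f"sex_{band}"] = cohens_d(*sa, *sb)
    for sex in sexes:
        for b1, b2 in zip(AGE_BANDS[:-1], AGE_BANDS[1:]):
            s1, s2 = stats(sex, b1), stats(sex, b2)
            if s1 and s2:
                effects[f"age_{b1}_vs_{b2}_{sex}"] = cohens_d(*s1, *s2)

    return CohortTable(strata=table, effect_sizes=effects)


# ---------------------------------------------------------------------------
# minimum-wear-time reliability

def icc_2_1(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measurement, for two measurements per subject."""
    data = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n, k = data.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom == 0:
        return 1.0 if msr == mse else 0.0
    return float((msr - mse) / denom)


@dataclass
class ReliabilityCurve:
    hours: np.ndarray
    icc: np.ndarray
    mc_se: np.ndarray       # Monte-Carlo SE of the mean ICC across replicates

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"hours": self.hours, "icc": self.icc,
                             "mc_se": self.mc_se})


def wear_reliability(cohort_epochs: Sequence[EpochSeries],
                     config: PipelineConfig,
                     hours_grid: Sequence[float] = DEFAULT_HOURS_GRID,
                     n_reps: int = 10,
                     seed: int = 0) -> ReliabilityCurve:
    """Reliability of truncated wear windows against the full measurement.

    For each grid value *h* and each replicate, a random contiguous h-hour
    sub-window is kept per participant, everything outside it is treated as
    non-wear and imputed, the outcome is recomputed, and ICC(2,1) between
    truncated and full outcomes is taken across participants.  Requires at
    least 10 fully compliant participants (the curve is unstable below that).
    """
    max_h = max(hours_grid)
    usable = []
    for es in cohort_epochs:
        wear_h = es.wear.sum() * es.epoch_s / 3600.0
        if wear_h >= max_h:
            usable.append(es)
    if len(usable) < 10:
        raise ValueError(
            f"need >=10 fully compliant participants, got {len(usable)}")

    full = np.array([overall_outcome(es) for es in usable])
    rng = np.random.default_rng(seed)
    eph = 3600 // usable[0].epoch_s   # epochs per hour

    iccs = np.empty((len(hours_grid), n_reps))
    for gi, h in enumerate(hours_grid):
        keep_n = int(round(h * eph))
        for rep in range(n_reps):
            truncated = np.empty(len(usable))
            for pi, es in enumerate(usable):
                n = len(es)
                lo = 0 if n <= keep_n else int(rng.integers(0, n - keep_n + 1))
                sub = es.copy()
                sub.wear[:lo] = False
                sub.wear[lo + keep_n:] = False
                sub.imputed[:] = False
                sub = impute_nonwear(sub, config)
                truncated[pi] = overall_outcome(sub)
            iccs[gi, rep] = icc_2_1(full, truncated)

    return ReliabilityCurve(
        hours=np.asarray(hours_grid, float),
        icc=iccs.mean(axis=1),
        mc_se=iccs.std(axis=1, ddof=1) / np.sqrt(n_reps),
    )
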