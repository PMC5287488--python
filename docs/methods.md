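# Methods

This note documents the processing model implemented by `wristpa`, the
choices made where the protocol leaves room, and what the synthetic-data
generator does and does not emulate.

## Processing model

The pipeline converts raw wrist-worn triaxial acceleration (nominally 100 Hz,
±8 g, in gravitational units *g*) into a participant-level physical-activity
outcome in milli-gravity (mg, 1 g = 1000 mg). Stages, in order:

1. **Gravity autocalibration.** During rest the sensor measures only gravity,
   so the mean acceleration vector of every stationary window (10 s,
   per-axis SD < 13 mg on all three axes) should lie on the unit sphere.
   Per-axis offset `o` and gain `k` are fitted so that
   `corrected = (raw − o)·k` minimises the distance of the window means to
   the sphere. A single least-squares pass cannot fit a sphere, so the fit
   iterates: project each corrected mean to its nearest sphere point, run
   per-axis OLS of corrected → projection, compose the update into the model,
   repeat until the largest coefficient change is < 1e-9 (or 1000
   iterations). When the recording carries a temperature channel, a linear
   per-axis temperature term (about the mean temperature) is added, bringing
   the model to 9 parameters; without temperature the model is the 6-parameter
   offset+gain core. A device is *uncalibratable* when any axis' window means
   fail to span ±300 mg or fewer than 10 windows exist; its coefficients are
   then borrowed from the previous — or failing that, the next — recording of
   the same physical device, and as a last resort the identity model is used
   with a warning. Fit quality is reported as the RMS of (‖v‖ − 1) over
   window means, before and after correction, in mg. Samples flagged as
   clipped (at or beyond ±8 g) are excluded from window statistics; clips are
   counted before and after calibration but never removed.
2. **Resampling.** Linear interpolation onto an exact uniform grid (default
   100 Hz). Gaps longer than 5 s are interrupts: grid points strictly inside
   them are missing, never interpolated.
3. **Vector magnitude.** Per-sample Euclidean norm √(x²+y²+z²).
4. **Noise filter.** Zero-phase (forward–backward) 4th-order Butterworth
   low-pass, 20 Hz cutoff, applied per contiguous non-missing segment. The
   double pass squares the magnitude response: DC gain is exactly 1 and the
   amplitude at the cutoff is 0.5 (not 1/√2); this is deliberate and tested.
   Segments shorter than the filter's padding length (≈16 samples for the
   SOS cascade) pass through unfiltered with a warning — slightly stricter
   than a 3×order rule, as the zero-phase filter is numerically undefined
   below its padding length.
5. **Gravity removal.** Primary metric: truncated Euclidean norm minus one,
   `ENMO = max(‖a‖ − 1, 0)` in mg. Variants kept for sensitivity analyses:
   absolute value `|‖a‖ − 1|`, and the high-pass-filtered, rectified vector
   magnitude (cutoff 0.2 Hz — the protocol does not state one; 0.2 Hz is our
   configurable default, low enough to keep multi-second activity bouts).
6. **Epochs.** 5-s means on the 5-s grid anchored at local midnight; partial
   boundary epochs are dropped; an epoch keeps the mean of its valid samples
   whatever its coverage (threshold-free), with the coverage recorded.
   All wall-clock constructs (epoch grid, minute-of-day, hour bins) use
   local time; on daylight-saving transitions civil labels are used as-is.
7. **Non-wear.** Maximal runs of consecutive, gap-free stationary windows
   spanning ≥ 60 min (inclusive) become non-wear episodes; overlapping
   epochs are flagged not-worn.
8. **Imputation.** Each non-worn or missing epoch is replaced by the mean
   worn value at the same minute of day on the other measured days. This
   removes diurnal wear bias: if the device is systematically off at night
   the crude worn mean overestimates true activity. Fallbacks (the protocol
   gives none): widen the pool to ±30 min of the slot on other days, then
   the participant's overall worn mean; both are flagged separately. Both
   the epoch value and its contribution to the intensity distribution are
   imputed.
9. **Outcomes.** Overall mean of worn+imputed epochs (mg); intensity ECDF
   (cumulative hours at or below 0, 5, …, 2000 mg; values above the top
   breakpoint are counted in the final bin so the curve saturates at total
   time); hourly and six-hour-quadrant profiles; weekday (Mon–Fri) vs
   weekend means; season from the first worn day with meteorological
   boundaries (Spring = 1 March). Inclusion requires ≥ 72 h of wear
   (boundary inclusive) *and* at least one worn epoch in each of the 24
   hour-of-day bins.

## Cohort statistics

Strata are sex × age band (45–54, 55–64, 65–74, 75–79): median (IQR) wear
time and mean ± SD vector magnitude, with Cohen's d
(pooled-SD standardised difference) for sex within band and adjacent bands.
The minimum-wear-time simulation keeps, for each fully compliant
participant, a random contiguous h-hour sub-window (h ∈ {24,…,168}, 10
replicates by default, seeded), treats everything outside it as non-wear,
re-imputes, recomputes the outcome, and reports ICC between truncated and
full outcomes. ICC flavour (unstated in the protocol): ICC(2,1) — two-way
random effects, absolute agreement, single measurement — computed from the
standard mean-squares decomposition and cross-checked against an independent
implementation in the tests. At h = 168 the truncated window is the full
measurement, so ICC = 1 by construction.

## Synthetic data

`simulate_participant` alternates rest bouts (fixed random orientation drawn
fresh whenever rest follows activity, plus per-axis Gaussian sensor noise,
5 mg default — a realistic post-filter device noise level, safely below the
13 mg stationarity threshold) with activity bouts (orientation random walk
on the sphere plus a rectified band-limited (0.5–10 Hz) Gaussian activity
component along the orientation). The activity amplitude is renormalised
within every wall-clock hour so the clean trace's mean truncated ENMO equals
that hour's diurnal target *exactly*; ground truth (overall and per-hour
means) is therefore known analytically before corruption. Miscalibration is
embedded invertibly (`stored = clean/gain + offset`), non-wear as still
low-noise blocks, interrupts as deleted samples, clips by pushing samples
beyond ±8 g. The default 24-h profile has quadrant means 4.4 / 38.6 / 44.3 /
26.4 mg (overall ≈ 28.4 mg), matching published diurnal activity shape;
cohort levels are drawn per age band (31 / 29 / 26.5 / 23.5 mg, SD 8 mg).

The generator emulates what the pipeline's logic depends on — stationary
geometry, diurnal structure, wear/non-wear contrast, between-person and
day-to-day variance — and *not* biomechanically realistic gait spectra,
temperature physics, or device-specific noise colour. Passing tests
therefore validate the algorithms' correctness and statistical behaviour,
not absolute real-world accuracy of any constant.

An epoch-level generator (`simulate_epoch_series`, `simulate_epoch_cohort`)
emits worn 5-s epochs directly (level × diurnal shape × lognormal day
multiplier × unit-mean gamma epoch noise). Imputation and reliability
operate on epochs, so cohort-scale tests of that machinery use this fast
path rather than synthesising raw signal for hundreds of participants.

## Problem sizes and scaled test conditions

Full-rate processing (100 Hz, 20 Hz cutoff) is exercised by the filter and
closed-form tests. Signal-level simulation tests run at proportionally
scaled rates (25 Hz with a 5 Hz cutoff, or 10 Hz with 2 Hz) and 0.05–2-day
durations, with the simulator's activity band scaled into the passband —
the pipeline is rate-agnostic and every constant scales through the
configuration. The reliability curve is computed on a 200-participant
epoch-level cohort (7 days each); the three gravity-removal metrics are
compared across a 20-participant signal-level cohort (1 day at 25 Hz).
End-to-end recovery uses 2-day recordings at 25 Hz with embedded
miscalibration and a 2-h non-wear block.

## Numerical choices and edge cases

- Convergence tolerance 1e-9 on calibration coefficients; per-axis OLS via
  `numpy.linalg.lstsq`.
- Window SDs use the sample (ddof = 1) estimator; the stationarity test is
  strict (`< 13 mg`), the non-wear duration test inclusive (`≥ 60 min`).
- Stationary windows are non-overlapping and aligned to the recording
  start; a window must be fully covered by samples (interrupt-free) and
  keep ≥ 2 unclipped samples.
- Epoch values with partial coverage keep the mean of valid samples; fully
  missing epochs are NaN until imputed.
- Timestamps are written at microsecond resolution; raw CSV round-trips are
  exact to < 1e-6 g and epoch/summary round-trips to < 1e-9.
- Recordings with no worn epochs at all are left unimputed (nothing to
  impute from); `overall_outcome` then raises.

## Known limitations

- Coefficient borrowing trusts the registry's chronology; no drift model
  between uses of a device.
- The ECDF grid is fixed (0–2000 mg in 5 mg steps) and top-codes higher
  epochs into the last bin.
- Daylight-saving transitions duplicate or skip one civil hour rather than
  shifting the grid.
- The simulator's infeasibility check rejects profiles whose hourly target
  is positive in an hour with no scheduled activity, but does not check
  attainability against the noise floor more finely.
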