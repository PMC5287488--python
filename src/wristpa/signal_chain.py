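"""Calibrated raw samples -> uniform, noise-filtered, gravity-removed signal.

Order of operations follows the processing protocol: resample to a uniform
grid with linear interpolation (gaps longer than 5 s become missing data and
are counted as interrupts), take the per-sample Euclidean norm, remove machine
noise with a zero-phase 4th-order Butterworth low-pass (20 Hz), then remove
the 1 g gravity component.  Three gravity-removal variants are provided:

* ``enmo_trunc`` — max(|a| − 1, 0), the primary activity metric;
* ``enmo_abs``   — abs(|a| − 1);
* ``highpass_vm`` — the vector magnitude high-pass filtered (0.2 Hz) and
  rectified.

Filtering is zero-phase (forward-backward), so the attenuation at the cutoff
is 0.5 in amplitude (two −3 dB passes), and it is applied independently to
each contiguous non-missing segment; the >5 s gap rule already decided what
is missing, and no filtering ever bridges a gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import PipelineConfig
from .errors import DataError
from .raw_io import RawRecording

GRAVITY_REMOVAL_MODES = ("enmo_trunc", "enmo_abs", "highpass_vm")


@dataclass
class UniformSignal:
    """A uniformly sampled signal with an aligned missing-data mask.

    ``values`` is (n,) for scalar signals or (n, 3) for triaxial ones; the
    mask is shared across channels.
    """

    start: pd.Timestamp
    rate_hz: float
    values: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if len(self.values) != len(self.missing):
            raise ValueError("values and missing mask length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def start_local(self) -> pd.Timestamp:
        if self.start.tzinfo is not None:
            return self.start.tz_localize(None)
        return self.start


def resample_with_gaps(rec: RawRecording, config: PipelineConfig) -> UniformSignal:
    """Linear interpolation onto an exact uniform grid.

    Grid points whose bracketing raw gap exceeds ``max_gap_s`` are marked
    missing; each such gap counts as one interrupt in the quality report.
    """
    if len(rec) == 0:
        raise DataError("cannot resample an empty recording")
    dt = 1.0 / config.resample_rate_hz
    t = rec.t
    n_out = int(np.floor((t[-1] - t[0]) / dt)) + 1
    tg = t[0] + np.arange(n_out) * dt

    values = np.empty((n_out, 3))
    for a in range(3):
        values[:, a] = np.interp(tg, t, rec.xyz[:, a])

    missing = np.zeros(n_out, dtype=bool)
    gaps = np.diff(t)
    big = np.flatnonzero(gaps > config.max_gap_s)
    for i in big:
        # strictly inside (t[i], t[i+1])
        lo = np.searchsorted(tg, t[i], side="right")
        hi = np.searchsorted(tg, t[i + 1], side="left")
        missing[lo:hi] = True
    rec.quality.interrupts = int(len(big))

    return UniformSignal(
        start=rec.start_time + pd.Timedelta(seconds=float(t[0])),
        rate_hz=config.resample_rate_hz,
        values=values,
        missing=missing,
    )


def vector_magnitude(signal: UniformSignal) -> UniformSignal:
    """Per-sample Euclidean norm of the three axes, in g."""
    if signal.values.ndim != 2 or signal.values.shape[1] != 3:
        raise ValueError("vector_magnitude expects a triaxial signal")
    vm = np.linalg.norm(signal.values, axis=1)
    return UniformSignal(signal.start, signal.rate_hz, vm, signal.missing.copy())


def _contiguous_segments(missing: np.ndarray):
    """Yield (start, stop) index pairs of maximal non-missing runs."""
    n = len(missing)
    i = 0
    while i < n:
        if missing[i]:
            i += 1
            continue
        j = i
        while j < n and not missing[j]:
            j += 1
        yield i, j
        i = j


def _filtfilt_segments(values: np.ndarray, missing: np.ndarray,
                       sos: np.ndarray, what: str) -> np.ndarray:
    out = values.copy()
    padlen = 3 * (2 * len(sos) + 1)
    for i, j in _contiguous_segments(missing):
        seg = values[i:j]
        if len(seg) <= padlen:
            warnings.warn(
                f"{what}: segment of {len(seg)} samples too short to filter; "
                "passed through unfiltered", stacklevel=2)
            continue
        out[i:j] = sps.sosfiltfilt(sos, seg)
    return out


def lowpass_noise_filter(signal: UniformSignal, config: PipelineConfig) -> UniformSignal:
    """Zero-phase Butterworth low-pass to remove machine noise.

    DC gain is exactly 1; amplitude at the cutoff is 0.5 because the
    forward-backward pass squares the magnitude response.
    """
    sos = sps.butter(config.filter_order, config.filter_cutoff_hz,
                     btype="low", fs=signal.rate_hz, output="sos")
    vals = _filtfilt_segments(signal.values, signal.missing, sos, "lowpass")
    vals[signal.missing] = np.nan
    return UniformSignal(signal.start, signal.rate_hz, vals, signal.missing.copy())


def remove_gravity(vm_signal: UniformSignal, mode: str,
                   config: PipelineConfig) -> UniformSignal:
    """Remove the 1 g gravity component from a scalar VM signal; output in mg.

    Missing samples propagate (NaN under the mask).
    """
    if mode not in GRAVITY_REMOVAL_MODES:
        raise ValueError(f"unknown gravity removal mode {mode!r}; "
                         f"expected one of {GRAVITY_REMOVAL_MODES}")
    vm = vm_signal.values
    if mode == "enmo_trunc":
        out = np.maximum(vm - 1.0, 0.0) * config.gravity_mg
    elif mode == "enmo_abs":
        out = np.abs(vm - 1.0) * config.gravity_mg
    else:  # highpass_vm
        sos = sps.butter(config.filter_order, config.highpass_cutoff_hz,
                         btype="high", fs=vm_signal.rate_hz, output="sos")
        hp = _filtfilt_segments(vm, vm_signal.missing, sos, "highpass_vm")
        out = np.abs(hp) * config.gravity_mg
    out = np.where(vm_signal.missing, np.nan, out)
    return UniformSignal(vm_signal.start, vm_signal.rate_hz, out,
                         vm_signal.missing.copy())
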