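"""Independent brute-force re-computations used as oracles in tests.

These deliberately share no code with the package implementations: plain
Python loops and pandas groupbys, O(n·w) where the package is vectorised.
"""

import numpy as np
import pandas as pd


def bf_stationary_window_indices(rec, config):
    """O(n·w) rescan: window index -> stationary?, via explicit slicing."""
    win_s = config.stationary_window_s
    expected = int(round(win_s * rec.nominal_rate_hz))
    n_win = int(rec.t[-1] // win_s) + 1
    out = []
    for w in range(n_win):
        sel = (rec.t >= w * win_s) & (rec.t < (w + 1) * win_s)
        if sel.sum() < expected:
            continue
        keep = sel & ~rec.clipped
        if keep.sum() < max(2, 0.5 * expected):
            continue
        sds = rec.xyz[keep].std(axis=0, ddof=1) * 1000.0
        if all(sd < config.stationary_sd_threshold_mg for sd in sds):
            out.append(w)
    return out


def bf_epoch_means(activity, config):
    """groupby-mean over 5-s wall-clock bins; returns a pandas Series indexed
    by epoch start, full epochs only."""
    ls = activity.start_local
    t = ls + pd.to_timedelta(np.arange(len(activity)) / activity.rate_hz, unit="s")
    df = pd.DataFrame({"t": t, "v": np.where(activity.missing, np.nan,
                                             activity.values)})
    df["epoch"] = df["t"].dt.floor(f"{config.epoch_s}s")
    g = df.groupby("epoch")["v"]
    counts = df.groupby("epoch")["t"].count()
    spe = int(round(config.epoch_s * activity.rate_hz))
    full = counts[counts == spe].index
    return g.mean().loc[full]


def bf_ecdf_hours(vm_mg, breakpoint_mg, epoch_s):
    """Counting oracle: hours of epochs with vm <= breakpoint."""
    return sum(1 for v in vm_mg if v <= breakpoint_mg) * epoch_s / 3600.0


def bf_wear_flags(epoch_starts, epoch_s, episodes):
    """O(n·m) interval-overlap scan."""
    flags = []
    for s in epoch_starts:
        e = s + pd.Timedelta(seconds=epoch_s)
        overlap = any(s < ep.end and e > ep.start for ep in episodes)
        flags.append(not overlap)
    return np.array(flags)
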