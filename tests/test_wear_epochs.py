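import numpy as np
import pandas as pd
import pytest

from wristpa.calibration import StationaryWindow, find_stationary_windows
from wristpa.pipeline import run_pipeline
from wristpa.signal_chain import (UniformSignal, lowpass_noise_filter,
                                  remove_gravity, resample_with_gaps,
                                  vector_magnitude)
from wristpa.synthetic_data import (SimScenario, simulate_epoch_series,
                                    simulate_participant)
from wristpa.wear_epochs import (EpochSeries, NonWearEpisode, check_inclusion,
                                 detect_nonwear, flag_wear, impute_nonwear,
                                 intensity_ecdf, make_epochs, overall_outcome)

from oracles import bf_ecdf_hours, bf_epoch_means, bf_wear_flags

START = pd.Timestamp("2014-05-12T10:00:00")


def scalar_signal(values, rate=10.0, missing=None, start=START):
    values = np.asarray(values, float)
    if missing is None:
        missing = np.zeros(len(values), dtype=bool)
    return UniformSignal(start, rate, values, missing)


def worn_series(vm, start=START, epoch_s=5):
    vm = np.asarray(vm, float)
    n = len(vm)
    return EpochSeries(start=start, epoch_s=epoch_s, vm_mg=vm,
                       wear=np.ones(n, dtype=bool),
                       imputed=np.zeros(n, dtype=bool),
                       valid_fraction=np.ones(n))


def windows_at(indices, start_base=START):
    return [StationaryWindow(index=int(i),
                             start=start_base + pd.Timedelta(seconds=10.0 * i),
                             mean_xyz=np.array([0.0, 0, 1]),
                             sd_mg=np.zeros(3), n=100)
            for i in indices]


class TestMakeEpochs:
    def test_constant_signal_two_epochs(self, config10):
        sig = scalar_signal(np.full(100, 40.0))  # 10 s at 10 Hz
        es = make_epochs(sig, config10)
        assert len(es) == 2
        assert np.allclose(es.vm_mg, 40.0)
        assert es.wear.all()

    def test_alternating_samples_average(self, config10):
        v = np.tile([0.0, 100.0], 50)
        es = make_epochs(scalar_signal(v), config10)
        assert np.allclose(es.vm_mg, 50.0)

    def test_partial_boundary_epochs_dropped(self, config10):
        sig = scalar_signal(np.full(95, 10.0),
                            start=START + pd.Timedelta(seconds=2))
        es = make_epochs(sig, config10)
        # 9.5 s starting at :02 -> only epoch [:05,:10) is fully covered
        assert len(es) == 1
        assert es.start == START + pd.Timedelta(seconds=5)

    def test_matches_groupby_oracle_on_simulated_day(self, config10):
        rec, _ = simulate_participant(
            SimScenario(seed=17, days=0.3, rate_hz=10, activity_band_hz=(0.5, 2),
                        interrupt_intervals=[(3600.0, 3610.0)]))
        sig = resample_with_gaps(rec, config10)
        act = remove_gravity(lowpass_noise_filter(vector_magnitude(sig),
                                                  config10),
                             "enmo_trunc", config10)
        es = make_epochs(act, config10)
        oracle = bf_epoch_means(act, config10)
        got = pd.Series(es.vm_mg, index=es.starts())
        common = oracle.index.intersection(got.index)
        assert len(common) == len(es)
        a, b = got.loc[common].to_numpy(), oracle.loc[common].to_numpy()
        both = np.isfinite(a) & np.isfinite(b)
        assert np.array_equal(np.isfinite(a), np.isfinite(b))
        assert np.max(np.abs(a[both] - b[both])) < 1e-9


class TestDetectNonwear:
    def test_70_min_run_is_one_episode(self, config):
        eps = detect_nonwear(windows_at(range(0, 420)), config)
        assert len(eps) == 1
        assert eps[0].duration_min == 70.0

    def test_just_under_60_min_is_nothing(self, config):
        eps = detect_nonwear(windows_at(range(0, 359)), config)
        assert eps == []

    def test_exactly_60_min_is_inclusive(self, config):
        eps = detect_nonwear(windows_at(range(0, 360)), config)
        assert len(eps) == 1
        assert eps[0].duration_min == 60.0

    def test_gap_breaks_run(self, config):
        idx = list(range(0, 200)) + list(range(201, 401))  # 2 runs < 60 min
        assert detect_nonwear(windows_at(idx), config) == []

    def test_detects_injected_episode_in_simulated_trace(self, config10):
        sc = SimScenario(seed=23, days=0.2, rate_hz=10,
                         activity_band_hz=(0.5, 2),
                         nonwear_intervals=[(2 * 3600.0, 2 * 3600.0 + 70 * 60)])
        rec, truth = simulate_participant(sc)
        ws = find_stationary_windows(rec, config10)
        eps = detect_nonwear(ws, config10)
        assert len(eps) == 1
        a, b = truth.true_nonwear[0]
        assert eps[0].start >= a - pd.Timedelta(minutes=1)
        assert eps[0].end <= b + pd.Timedelta(minutes=1)
        assert eps[0].duration_min >= 60.0


class TestFlagWear:
    def test_no_episodes_all_valid_worn(self):
        es = flag_wear(worn_series(np.ones(100)), [])
        assert es.wear.all()

    def test_full_hour_episode_flags_720_epochs(self):
        es = worn_series(np.ones(3 * 720), start=pd.Timestamp("2014-05-12"))
        ep = NonWearEpisode(pd.Timestamp("2014-05-12T02:00:00"),
                            pd.Timestamp("2014-05-12T03:00:00"))
        out = flag_wear(es, [ep])
        assert (~out.wear).sum() == 720
        assert not out.wear[2 * 720:3 * 720].any()

    def test_fuzz_against_interval_overlap_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            n = 500
            es = worn_series(np.ones(n))
            eps = []
            for _ in range(rng.integers(1, 6)):
                a = float(rng.uniform(-100, n * 5 + 100))
                d = float(rng.uniform(1, 900))
                eps.append(NonWearEpisode(START + pd.Timedelta(seconds=a),
                                          START + pd.Timedelta(seconds=a + d)))
            out = flag_wear(es, eps)
            oracle = bf_wear_flags(list(es.starts()), 5, eps)
            assert np.array_equal(out.wear, oracle)


class TestImpute:
    def test_slot_filled_with_other_day_mean(self, config):
        # 3 days of one 5-s epoch per day at the same wall-clock slot
        start = pd.Timestamp("2014-05-12T08:00:00")
        vm = np.zeros(3 * 17280)
        es = EpochSeries(start=start, epoch_s=5, vm_mg=vm,
                         wear=np.ones(len(vm), dtype=bool),
                         imputed=np.zeros(len(vm), dtype=bool),
                         valid_fraction=np.ones(len(vm)))
        slot = 120  # some epoch within day 1
        day = 17280
        es.vm_mg[:] = 5.0
        # worn values 10 and 20 at this minute slot on days 1-2; missing day 3
        minute = slice(slot - slot % 12, slot - slot % 12 + 12)
        es.vm_mg[minute] = 10.0
        es.vm_mg[day + slot - slot % 12: day + slot - slot % 12 + 12] = 20.0
        tgt = slice(2 * day + slot - slot % 12, 2 * day + slot - slot % 12 + 12)
        es.wear[tgt] = False
        out = impute_nonwear(es, config)
        assert np.allclose(out.vm_mg[tgt], 15.0)
        assert out.imputed[tgt].all()
        assert not out.fallback_imputed[tgt].any()

    def test_no_nonwear_is_identity(self, config):
        es, _ = simulate_epoch_series(seed=3, days=2)
        out = impute_nonwear(es, config)
        assert np.array_equal(out.vm_mg, es.vm_mg)
        assert not out.imputed.any()

    def test_worn_epochs_untouched_bitwise(self, config):
        es, _ = simulate_epoch_series(seed=4, days=3)
        es.wear[1000:3000] = False
        before = es.vm_mg.copy()
        out = impute_nonwear(es, config)
        assert np.array_equal(out.vm_mg[out.wear], before[out.wear])

    def test_conservation_of_epoch_counts(self, config):
        es, _ = simulate_epoch_series(seed=5, days=3)
        es.wear[2000:9000] = False
        out = impute_nonwear(es, config)
        assert (out.wear.sum() + out.imputed.sum()
                + ((~out.wear) & (~out.imputed)).sum()) == len(out)
        assert ((~out.wear) & (~out.imputed)).sum() == 0  # all imputable here

    def test_night_biased_missingness(self, config):
        """Random or night-biased removal: imputed mean tracks truth, the
        worn-only mean overestimates under night bias."""
        es, truth = simulate_epoch_series(seed=6, days=7)
        # nights 00:00-06:00 missing on days 1, 3, 5
        hour, day = es.hour_of_day(), es.day_index()
        drop = (hour < 6) & np.isin(day, [1, 3, 5])
        es.wear[drop] = False
        worn_only = es.vm_mg[es.wear].mean()
        out = impute_nonwear(es, config)
        imputed_mean = overall_outcome(out)
        assert abs(imputed_mean - truth) / truth < 0.02
        assert abs(worn_only - truth) > abs(imputed_mean - truth)


class TestEcdf:
    def test_all_zero_saturates_at_first_breakpoint(self, config):
        es = worn_series(np.zeros(720))
        e = intensity_ecdf(es, config)
        assert e.cum_time_h[0] == 1.0  # 720 epochs * 5 s = 1 h
        assert e.cum_time_h[-1] == 1.0

    def test_half_low_half_high(self, config):
        es = worn_series(np.r_[np.full(360, 10.0), np.full(360, 100.0)])
        e = intensity_ecdf(es, config)
        b25 = np.flatnonzero(e.grid_mg == 25.0)[0]
        assert e.cum_time_h[b25] == 0.5

    def test_counting_oracle_and_monotonicity(self, config):
        es, _ = simulate_epoch_series(seed=8, days=7)
        e = intensity_ecdf(es, config)
        assert bf_ecdf_hours(es.vm_mg, 25.0, 5) == e.cum_time_h[
            np.flatnonzero(e.grid_mg == 25.0)[0]]
        assert np.all(np.diff(e.cum_time_h) >= 0)
        assert np.isclose(e.cum_time_h[-1], len(es) * 5 / 3600.0)


class TestOutcomeAndInclusion:
    def test_constant_and_mixed_means(self, config):
        assert overall_outcome(worn_series(np.full(100, 30.0))) == 30.0
        assert overall_outcome(
            worn_series(np.r_[np.zeros(50), np.full(50, 60.0)])) == 30.0

    def test_simulated_mean_matches_bruteforce(self, config):
        es, _ = simulate_epoch_series(seed=9, days=2)
        mask = es.wear | es.imputed
        assert abs(overall_outcome(es) - float(np.mean(es.vm_mg[mask]))) < 1e-9

    def test_no_usable_epochs_is_error(self, config):
        es = worn_series(np.ones(10))
        es.wear[:] = False
        with pytest.raises(ValueError):
            overall_outcome(es)

    def test_72h_boundary(self, config):
        es, _ = simulate_epoch_series(seed=10, days=7)
        n72 = 72 * 720
        es.wear[n72:] = False
        r = check_inclusion(es, config)
        assert r.included and r.wear_hours == 72.0

        es.wear[n72 - 1] = False  # 71.99h, rounds below the threshold
        r2 = check_inclusion(es, config)
        assert not r2.included
        assert "72" in r2.reason

    def test_missing_hour_bin_excludes(self, config):
        es, _ = simulate_epoch_series(seed=11, days=7)
        hour = es.hour_of_day()
        es.wear[hour == 3] = False
        r = check_inclusion(es, config)
        assert not r.included
        assert r.covered_hour_bins == 23
        assert "coverage" in r.reason

    def test_full_week_is_included(self, config):
        es, _ = simulate_epoch_series(seed=12, days=7)
        r = check_inclusion(es, config)
        assert r.included and r.wear_hours == 168.0 and r.covered_hour_bins == 24
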