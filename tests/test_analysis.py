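"""Behavioral quantification: binning, smoothing, actograms, folding,
FAA ratios, bout detection, period regression and periodograms."""

import numpy as np
import pytest

from feosim import (
    ActivityRecord,
    BoutEstimate,
    FeedingProtocol,
    MealEvent,
    ProtocolSegment,
    bin_activity,
    chi_square_periodogram,
    detect_bouts,
    estimate_period,
    faa_ratio,
    fold_modulo,
    lomb_scargle,
    make_actogram,
    running_average,
)
from feosim.model import ActivitySeries


def record_from(counts, bin_width=10.0, start=0.0):
    return ActivityRecord(bin_width=bin_width, counts=np.asarray(counts, float), start=start)


class TestBinActivity:
    def test_event_counts_land_in_first_bin(self):
        rec = bin_activity(np.full(6, 5 / 60), bin_width=10.0, span=1.0)
        assert rec.counts[0] == 6
        assert rec.counts[1:].sum() == 0

    def test_constant_series_bins_to_constant(self):
        t = np.arange(0, 24, 1 / 6)
        s = ActivitySeries(times=t, chi=np.zeros_like(t), activity=np.full_like(t, 0.5))
        rec = bin_activity(s, 10.0)
        assert np.allclose(rec.counts, 0.5)

    def test_rebinning_conserves_event_totals(self, rng):
        events = rng.uniform(0, 24, 500)
        fine = bin_activity(events, bin_width=1.0, span=24.0)
        coarse = bin_activity(events, bin_width=10.0, span=24.0)
        assert fine.counts.sum() == coarse.counts.sum() == 500

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bin_activity(np.array([]), 10.0)


class TestRunningAverage:
    def test_constant_unchanged(self):
        rec = record_from(np.full(50, 3.0))
        assert np.allclose(running_average(rec, 40.0).counts, 3.0)

    def test_unit_impulse_spreads_over_window(self):
        x = np.zeros(20)
        x[10] = 1.0
        sm = running_average(record_from(x), 40.0).counts
        # 4-bin centered window covering [i-2, i+1]: bins 9..12 see the impulse
        assert np.allclose(sm[9:13], 0.25)
        assert sm[8] == 0 and sm[13] == 0

    def test_linear_ramp_unchanged_in_interior(self):
        rec = record_from(np.arange(30.0))
        sm = running_average(rec, 40.0).counts
        interior = slice(3, -3)
        assert np.allclose(sm[interior], np.arange(30.0)[interior] - 0.5)

    def test_window_narrower_than_bin_rejected(self):
        with pytest.raises(ValueError):
            running_average(record_from(np.ones(10)), 5.0)


class TestActogram:
    def test_all_zero_record(self):
        rec = record_from(np.zeros(288))  # 2 days of 10-min bins
        raster = make_actogram(rec)
        assert raster.rows.shape == (2, 144)
        assert np.all(raster.rows == 0)

    def test_quintile_ranks(self):
        counts = np.zeros(144)
        counts[:100] = np.arange(1, 101)
        raster = make_actogram(record_from(counts, bin_width=10.0), day_length=24.0)
        ranks = raster.rows[0, :100]
        assert np.all(ranks[:20] == 1)  # counts 1..20 are <= 20th percentile
        assert np.all(ranks[-19:] == 5)  # counts > 80th percentile
        assert np.all(raster.rows[0, 100:] == 0)

    def test_modulo_26_actogram_aligns_pure_26h_rhythm(self):
        bw_h = 1 / 6
        n = int(26 * 6 * 8)  # 8 cycles of 26 h
        t = np.arange(n) * bw_h
        counts = (np.mod(t, 26.0) < 2.0).astype(float)
        raster = make_actogram(record_from(counts), day_length=26.0)
        active_cols = [set(np.nonzero(row)[0]) for row in raster.rows]
        assert all(cols == active_cols[0] for cols in active_cols)

    def test_double_plot_concatenates_next_day(self):
        counts = np.concatenate([np.ones(144), np.zeros(144)])
        raster = make_actogram(record_from(counts), double_plotted=True)
        assert raster.rows.shape == (2, 288)
        assert np.all(raster.rows[0, :144] > 0)
        assert np.all(raster.rows[0, 144:] == 0)

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            make_actogram(record_from(np.ones(10)))


class TestFoldModulo:
    def test_pure_periodic_signal_zero_sem(self):
        t = np.arange(0, 24 * 6, 1 / 6)
        counts = np.cos(2 * np.pi * t / 24.0) + 2.0
        phase, mean, sem = fold_modulo(record_from(counts), 24.0)
        assert np.allclose(sem, 0.0, atol=1e-12)
        assert np.allclose(mean, np.cos(2 * np.pi * phase / 24.0) + 2.0)

    def test_mismatched_fold_flattens_waveform(self):
        t = np.arange(0, 26 * 6 * 12, 1 / 6)  # 12 cycles of 26 h
        counts = np.cos(2 * np.pi * t / 24.0) + 2.0
        rec = record_from(counts)
        _, m24, _ = fold_modulo(rec, 24.0)
        _, m26, _ = fold_modulo(rec, 26.0)
        assert np.ptp(m26) < 0.2 * np.ptp(m24)

    def test_single_cycle_rejected(self):
        rec = record_from(np.ones(150))
        with pytest.raises(ValueError):
            fold_modulo(rec, 24.0)


def three_meal_day(duration=0.5):
    events = [MealEvent(z, duration) for z in (2.0, 10.0, 18.0)]
    return FeedingProtocol(events=events, segments=[ProtocolSegment(0.0, 24.0)])


class TestFaaRatio:
    def test_all_premeal_activity_sums_to_one(self):
        prot = three_meal_day()
        counts = np.zeros(144)
        for z in (2.0, 10.0, 18.0):
            i = int(z * 6)
            counts[i - 12:i] = 1.0  # activity only in the 2 h before each meal
        ratios = faa_ratio(record_from(counts), prot, window=2.0, denominator_mode="whole_day")
        assert sum(r.ratio for r in ratios) == pytest.approx(1.0)

    def test_uniform_activity_intermeal_ratio(self):
        """8-h spacing, 0.5-h meals, 2-h window: each intermeal interval is
        7.5 h, so the ratio is 2 / 7.5."""
        prot = three_meal_day()
        ratios = faa_ratio(record_from(np.ones(144)), prot, 2.0, "intermeal")
        for r in ratios[1:]:  # first meal's interval is clipped by the record start
            assert r.ratio == pytest.approx(2.0 / 7.5)

    def test_whole_day_ratios_sum_below_one(self, rng):
        prot = three_meal_day()
        ratios = faa_ratio(record_from(rng.uniform(0, 1, 144)), prot, 2.0, "whole_day")
        assert 0 < sum(r.ratio for r in ratios) <= 1.0

    def test_zero_activity_degenerate_flag(self):
        prot = three_meal_day()
        ratios = faa_ratio(record_from(np.zeros(144)), prot, 2.0, "whole_day")
        assert all(r.ratio == 0.0 and r.degenerate for r in ratios)

    def test_window_overlapping_previous_meal_rejected(self):
        prot = three_meal_day()
        with pytest.raises(ValueError, match="overlaps"):
            faa_ratio(record_from(np.ones(144)), prot, window=7.9)


class TestDetectBouts:
    def gaussian_record(self, center=17.0, sd=0.75, span=24.0):
        t = (np.arange(int(span * 6)) + 0.5) / 6
        return record_from(20 * np.exp(-0.5 * ((t - center) / sd) ** 2))

    def test_symmetric_bump_center_recovered(self):
        rec = self.gaussian_record(center=17.0)
        bouts = detect_bouts(rec, [(12.0, 22.0)], smoothing=40.0)
        assert len(bouts) == 1
        assert bouts[0].center == pytest.approx(17.0, abs=1 / 6)
        assert bouts[0].onset < 17.0 < bouts[0].end

    def test_flat_record_yields_no_bouts(self):
        rec = record_from(np.zeros(144))
        assert detect_bouts(rec, [(2.0, 10.0)]) == []

    def test_two_bumps_merge_into_single_bout(self):
        t = (np.arange(144) + 0.5) / 6
        counts = 10 * np.exp(-0.5 * ((t - 6.0) / 0.5) ** 2)
        counts += 10 * np.exp(-0.5 * ((t - 12.0) / 0.5) ** 2)
        bouts = detect_bouts(record_from(counts), [(2.0, 16.0)])
        assert len(bouts) == 1
        assert bouts[0].onset < 6.5 and bouts[0].end > 11.5

    def test_overlapping_windows_rejected(self):
        rec = record_from(np.ones(144))
        with pytest.raises(ValueError, match="overlap"):
            detect_bouts(rec, [(2.0, 10.0), (8.0, 16.0)])

    def test_centroid_option(self):
        rec = self.gaussian_record(center=17.0)
        bouts = detect_bouts(rec, [(12.0, 22.0)], center="centroid")
        assert bouts[0].center == pytest.approx(17.0, abs=0.2)


class TestEstimatePeriod:
    @staticmethod
    def bouts_from_centers(centers):
        return [
            BoutEstimate(onset=c - 1, end=c + 1, center=c, cycle_index=i)
            for i, c in enumerate(centers)
        ]

    def test_exact_line(self):
        fit = estimate_period(self.bouts_from_centers([17.0, 41.0, 65.0]))
        assert fit.period == pytest.approx(24.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_ols_slope_matches_closed_form(self):
        # closed form: sum((x-x̄)(y-ȳ)) / sum((x-x̄)^2) = 130.25 / 5
        fit = estimate_period(self.bouts_from_centers([10.0, 36.1, 62.0, 88.2]))
        assert fit.period == pytest.approx(26.05, abs=1e-9)
        assert fit.n_bouts == 4

    def test_single_bout_rejected(self):
        with pytest.raises(ValueError):
            estimate_period(self.bouts_from_centers([17.0]))


class TestChiSquarePeriodogram:
    def test_square_wave_peaks_at_true_period(self):
        t = np.arange(0, 240, 1 / 6)
        counts = (np.mod(t, 24.0) < 6.0).astype(float) * 10
        res = chi_square_periodogram(record_from(counts))
        assert res.peak_period == pytest.approx(24.0, abs=1e-9)
        i = np.argmax(res.power)
        assert res.power[i] > res.significance[i]

    def test_white_noise_rarely_significant_familywise(self):
        """Under the null no trial period should clear a family-wise 0.05
        line (Bonferroni over the period grid) in nearly all replicates."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rec = record_from(rng.poisson(5.0, 10 * 144).astype(float))
            res = chi_square_periodogram(rec, alpha=0.05 / 49)
            if np.any(res.power > res.significance):
                hits += 1
        assert hits <= 1

    def test_constant_record_zero_power(self):
        res = chi_square_periodogram(record_from(np.full(10 * 144, 2.0)))
        assert np.all(res.power == 0)

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            chi_square_periodogram(record_from(np.ones(144)))


class TestLombScargle:
    def test_pure_26h_sinusoid_peak(self):
        t = np.arange(0, 26 * 12, 1 / 6)
        counts = 5 + np.sin(2 * np.pi * t / 26.0)
        res = lomb_scargle(record_from(counts))
        assert res.peak_period == pytest.approx(26.0, abs=0.2)

    def test_two_component_signal_resolves_both_peaks(self):
        t = np.arange(0, 24 * 26, 1 / 6)  # two full 312-h beat periods
        counts = 5 + np.sin(2 * np.pi * t / 24.0) + np.sin(2 * np.pi * t / 26.0)
        freqs = np.linspace(1 / 30, 1 / 20, 600)
        res = lomb_scargle(record_from(counts), freqs)
        power = res.power
        peaks = [
            i for i in range(1, len(power) - 1)
            if power[i] > power[i - 1] and power[i] > power[i + 1] and power[i] > 0.2
        ]
        periods = sorted(res.periods[peaks])
        assert any(abs(p - 24.0) < 0.3 for p in periods)
        assert any(abs(p - 26.0) < 0.3 for p in periods)

    def test_constant_record_zero_power(self):
        res = lomb_scargle(record_from(np.full(288, 3.0)))
        assert np.all(res.power == 0)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            lomb_scargle(record_from(np.ones(288)), np.array([0.04]))
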