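"""Stimulus-locked functional analysis: regressors, pixelwise tuning,
responsiveness tests, PSTHs, phase binning, cross-correlation, and
behavioural epoch selection."""

import numpy as np
import pytest

from voltscope import funcmap, synthgen
from voltscope.funcmap import (build_regressors, crosscorr_lag,
                               normalize_movie, phase_bin_lowfreq,
                               pixelwise_tuning, psth,
                               select_behavior_epochs, tuning_curve,
                               visual_responsiveness)
from voltscope.types import Movie, Trace


class TestRegressors:
    SCHED = np.array([[1.0, 1.5, 0.0], [3.0, 3.5, 90.0]])

    def test_zero_before_onset(self):
        t = np.array([0.0, 0.5, 0.99])
        reg = build_regressors(self.SCHED, t)
        assert np.all(reg.matrix == 0.0)

    def test_closed_form_at_tau(self):
        tau = 0.7
        sched = np.array([[1.0, 2.0, 0.0]])  # trial longer than tau
        t = np.array([1.0 + tau])  # one tau into the trial, before offset
        reg = build_regressors(sched, t, tau_s=tau)
        assert reg.matrix[0, 0] == pytest.approx(1 - np.exp(-1))

    def test_decays_to_zero_long_after_offset(self):
        t = np.array([30.0])
        reg = build_regressors(self.SCHED, t)
        assert np.all(np.abs(reg.matrix) < 1e-12)

    def test_columns_zero_outside_own_trials(self):
        t = np.linspace(0, 5, 200)
        reg = build_regressors(self.SCHED, t)
        # the 90-degree column is zero until its trial starts at t = 3
        assert np.all(reg.matrix[t < 3.0, 1] == 0.0)
        assert np.all((reg.matrix >= 0) & (reg.matrix < 1))


class TestPixelwiseTuning:
    def _movie_from_cells(self, dff, frame_rate):
        n_cells, n_frames = dff.shape
        side = int(np.ceil(np.sqrt(n_cells)))
        data = np.zeros((n_frames, side * side))
        data[:, :n_cells] = dff.T
        return Movie(data.reshape(n_frames, side, side) + 100.0, frame_rate)

    def test_delta_tuned_pixel_phase_zero(self):
        dff, sched, truth = synthgen.simulate_population(
            "grating_tuned",
            {"kappa": 8.0, "preferred_deg": [0.0], "noise_sd": 0.0,
             "n_trials": 4, "shuffle": False}, seed=0)
        fr = truth.params["frame_rate"]
        movie = self._movie_from_cells(dff, fr)
        reg = build_regressors(sched, movie.times)
        tm = pixelwise_tuning(normalize_movie(movie), reg)
        pref = tm.preferred_deg.ravel()[0]
        err = min(pref, 180 - pref)
        assert err < 5.0

    def test_orientation_symmetric_response_cancels_exactly(self):
        """A pixel responding identically to all directions has complex
        projection exactly zero (the cancellation identity)."""
        n_dir = 8
        dirs = np.arange(n_dir) * 45.0
        coef = np.ones((n_dir, 1))
        basis = np.exp(2j * np.deg2rad(dirs)) / np.sqrt(n_dir / 2)
        assert abs((basis[:, None] * coef).sum()) < 1e-12

    def test_generator_population_recovered_within_10_degrees(self):
        prefs = [0.0, 30.0, 60.0, 90.0, 120.0, 150.0]
        dff, sched, truth = synthgen.simulate_population(
            "grating_tuned",
            {"kappa": 2.0, "preferred_deg": prefs, "noise_sd": 0.2,
             "n_trials": 10}, seed=1)
        fr = truth.params["frame_rate"]
        movie = self._movie_from_cells(dff, fr)
        reg = build_regressors(sched, movie.times)
        tm = pixelwise_tuning(normalize_movie(movie), reg)
        est = tm.preferred_deg.ravel()[: len(prefs)]
        err = np.abs((est - np.asarray(prefs) + 90) % 180 - 90)
        assert err.max() < 10.0

    def test_rank_deficient_design_rejected(self):
        sched = np.array([[1.0, 1.5, 0.0], [1.0, 1.5, 90.0]])
        t = np.linspace(0, 3, 100)
        reg = build_regressors(sched, t)
        movie = np.zeros((100, 2, 2))
        with pytest.raises(ValueError, match="rank"):
            pixelwise_tuning(movie, reg)


class TestTuningCurve:
    def test_flat_for_untuned_cell(self):
        sched = synthgen._grating_schedule(4, 5)
        t = np.arange(0, sched[-1, 1] + 0.5, 1 / 100.0)
        dff = Trace(np.full(t.size, 0.3), 100.0, units="dff")
        dirs, mean, sem, n = tuning_curve(dff, sched)
        assert np.allclose(mean, 0.3)
        assert np.all(n == 5)

    def test_single_peak_for_delta_tuned_cell(self):
        dff, sched, truth = synthgen.simulate_population(
            "grating_tuned",
            {"kappa": np.inf, "preferred_deg": [90.0], "noise_sd": 0.0,
             "n_trials": 3, "shuffle": False}, seed=2)
        fr = truth.params["frame_rate"]
        tr = Trace(dff[0], fr, units="dff")
        dirs, mean, sem, n = tuning_curve(tr, sched)
        peaked = dirs[np.nanargmax(mean)]
        assert peaked % 180.0 == 90.0

    def test_missing_direction_flagged(self):
        sched = np.array([[0.5, 1.0, 0.0], [1.5, 2.0, 0.0],
                          [2.5, 3.0, 90.0]])
        dff = Trace(np.zeros(400), 100.0, units="dff")
        sched_gap = sched[sched[:, 2] == 0.0]
        dirs, mean, sem, n = tuning_curve(dff, np.vstack(
            [sched_gap, [10.0, 10.5, 90.0]]))  # 90-degree trial out of range
        assert n[dirs == 90.0][0] == 0
        assert np.isnan(mean[dirs == 90.0][0])


class TestVisualResponsiveness:
    def test_null_rarely_significant(self):
        """Family-corrected test keeps the false-positive rate at or below
        alpha under the null (simulated)."""
        rng = np.random.default_rng(3)
        hits = 0
        n_cells = 200
        for _ in range(n_cells):
            stim = {d: rng.normal(0, 1, 8) for d in range(8)}
            blank = {d: rng.normal(0, 1, 8) for d in range(8)}
            vr, _ = visual_responsiveness(stim, blank)
            hits += vr
        # binomial 3-sigma bound around alpha = 0.05
        assert hits / n_cells < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_cells)

    def test_strong_rate_increase_detected(self):
        rng = np.random.default_rng(4)
        stim = {d: rng.normal(8, 1, 10) for d in range(8)}  # 8-fold increase
        blank = {d: rng.normal(1, 1, 10) for d in range(8)}
        vr, pvals = visual_responsiveness(stim, blank)
        assert vr
        assert min(pvals.values()) < 0.05 / 8

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError, match="2 trials"):
            visual_responsiveness({0: [1.0]}, {0: [0.5, 0.6]})


class TestPsth:
    def test_empty_trains_all_zero(self):
        centers, rate = psth([np.array([])], [0.0, 5.0])
        assert np.all(rate == 0.0)

    def test_homogeneous_poisson_flat(self):
        rng = np.random.default_rng(5)
        trains = [np.sort(rng.uniform(0, 100, 2000))]
        aligns = np.arange(5, 95, 5.0)
        centers, rate = psth(trains, aligns, window_s=(-0.5, 0.5))
        assert rate.mean() == pytest.approx(20.0, rel=0.1)
        assert rate.std() / rate.mean() < 0.5

    def test_count_conservation(self):
        trains = [np.array([0.105, 0.205, 0.255])]
        centers, rate = psth(trains, [0.0], window_s=(0.0, 0.5), bin_ms=10)
        assert rate.sum() * 0.01 == pytest.approx(3.0)


class TestPhaseBinning:
    def test_injected_coupling_phase_recovered_within_one_bin(self):
        v, m, truth = synthgen.simulate_population(
            "ach_coupled", {"duration_s": 120, "lag_rad": 1.0}, seed=6)
        prof = phase_bin_lowfreq(v, m)
        peak = prof.bin_centers[np.nanargmax(prof.mean)]
        assert abs(peak - truth.params["lag_rad"]) <= 2 * np.pi / 65 + 1e-9

    def test_phase_independent_amplitude_flat(self):
        rng = np.random.default_rng(7)
        fs = 395.0
        n = int(120 * fs)
        t = (np.arange(n) + 0.5) / fs
        v = Trace(np.sin(2 * np.pi * 5 * t) + 0.05 * rng.standard_normal(n),
                  fs, units="dff")
        m = Trace(np.cos(2 * np.pi * 0.3 * t), fs, units="dff")
        prof = phase_bin_lowfreq(v, m)
        spread = np.nanmax(prof.mean) - np.nanmin(prof.mean)
        # flat: spread is far below the modulation an injected coupling of
        # depth ~0.8 produces (order 0.5 in these units)
        assert spread < 0.05

    def test_profile_structure(self):
        v, m, _ = synthgen.simulate_population(
            "ach_coupled", {"duration_s": 60}, seed=8)
        prof = phase_bin_lowfreq(v, m)
        assert prof.bin_centers.size == 65
        assert np.all(prof.sem[~np.isnan(prof.sem)] >= 0)
        assert prof.smoothed

    def test_empty_epochs_rejected(self):
        v, m, _ = synthgen.simulate_population(
            "ach_coupled", {"duration_s": 30}, seed=9)
        with pytest.raises(ValueError, match="epoch"):
            phase_bin_lowfreq(v, m, epochs=[(100.0, 101.0)])


class TestCrossCorrelation:
    def _slow_noise(self, seed, n=6000, fs=100.0):
        from scipy.ndimage import uniform_filter1d
        rng = np.random.default_rng(seed)
        return uniform_filter1d(rng.normal(0, 1, n), 30), fs

    def test_self_correlation_peaks_at_zero_with_unit_value(self):
        x, fs = self._slow_noise(10)
        lags, corr, peak = crosscorr_lag(Trace(x, fs), Trace(x, fs),
                                         band_hz=None)
        assert peak == 0.0
        assert corr.max() == pytest.approx(1.0, abs=1e-9)

    def test_half_second_delay_recovered(self):
        x, fs = self._slow_noise(11)
        y = np.roll(x, 50)  # +0.5 s at 100 Hz
        _, _, peak = crosscorr_lag(Trace(x, fs), Trace(y, fs))
        assert peak == pytest.approx(0.5, abs=1 / fs)

    def test_independent_noise_small_peak(self):
        x, fs = self._slow_noise(12)
        y, _ = self._slow_noise(13)
        _, corr, peak = crosscorr_lag(Trace(x, fs), Trace(y, fs))
        lags_window = np.abs(peak) <= 1.5
        assert abs(corr.max()) < 0.5

    def test_mismatched_traces_rejected(self):
        with pytest.raises(ValueError, match="co-sampled"):
            crosscorr_lag(Trace(np.zeros(100), 10.0),
                          Trace(np.zeros(50), 10.0))


class TestBehaviorEpochs:
    def _pupil_cycle(self, fs=20.0, dur=40.0):
        """One clean dilation (10 s) followed by a fast constriction."""
        t = np.arange(0, dur, 1 / fs)
        d = np.full(t.size, 1.0)
        rise = (t >= 5) & (t < 15)
        d[rise] = 1.0 + 0.1 * (t[rise] - 5)  # slow dilation, 10 s
        fall = (t >= 15) & (t < 17)
        d[fall] = 2.0 - 0.5 * (t[fall] - 15)  # constriction at 0.5 mm/s
        d[t >= 17] = 1.0
        return t, d, fs

    def test_clean_cycle_yields_one_epoch(self):
        t, d, fs = self._pupil_cycle()
        run = Trace(np.zeros(t.size), fs)
        epochs, audit = select_behavior_epochs(Trace(d, fs), run)
        assert len(epochs) == 1
        a, b = epochs[0]
        assert a == pytest.approx(5.0, abs=1.0)

    def test_nan_heavy_epoch_excluded(self):
        t, d, fs = self._pupil_cycle()
        d[(t >= 5) & (t < 15)] = np.nan  # 10 s NaN: ~29% of the epoch
        run = Trace(np.zeros(t.size), fs)
        epochs, audit = select_behavior_epochs(Trace(d, fs), run)
        assert len(epochs) == 0
        assert any(reason == "nan_fraction" for *_, reason in audit)

    def test_running_burst_excludes_epoch(self):
        t, d, fs = self._pupil_cycle()
        speed = np.zeros(t.size)
        speed[(t >= 9) & (t < 11)] = 5.0  # 2-s run inside the epoch
        epochs, audit = select_behavior_epochs(Trace(d, fs),
                                               Trace(speed, fs))
        assert len(epochs) == 0
        assert any(reason == "running" for *_, reason in audit)

    def test_brief_running_blip_ignored(self):
        """Speed above threshold for less than 1 s is not a running period."""
        t, d, fs = self._pupil_cycle()
        speed = np.zeros(t.size)
        speed[(t >= 9) & (t < 9.4)] = 5.0  # 0.4-s blip
        epochs, _ = select_behavior_epochs(Trace(d, fs), Trace(speed, fs))
        assert len(epochs) == 1
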