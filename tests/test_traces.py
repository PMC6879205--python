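"""Trace analysis: dF/F0, bleach correction, spontaneous stats, correlations, 4PL."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribbonquant import synthdata as S
from ribbonquant import traces as T


def cyto_only(**kw):
    base = dict(
        frame_rate=1 / 3, duration=900.0, stimulus_windows=(), noise_sd=0.0,
        n_cells=1, kinetics={"cyto": S.ChannelKinetics(0.06, 3.0)},
    )
    base.update(kw)
    return S.TraceSimSpec(**base)


class TestRegisterTranslation:
    def test_zero_drift_zero_shifts(self):
        rng = np.random.default_rng(0)
        frame = rng.random((32, 32))
        movie = np.stack([frame] * 4)
        _, shifts = T.register_translation(movie)
        assert np.all(shifts == 0)

    def test_planted_drift_recovered(self):
        rng = np.random.default_rng(1)
        frame = rng.random((48, 48)) * 10
        movie = np.stack([frame, np.roll(frame, 3, axis=1), np.roll(frame, 3, axis=1)])
        aligned, shifts = T.register_translation(movie)
        assert shifts.tolist() == [[0, 0], [0, 3], [0, 3]]
        # interior pixels restored (edges are padding)
        np.testing.assert_allclose(aligned[1][5:-5, 5:-5], frame[5:-5, 5:-5])

    def test_constant_movie_tie_breaks_to_zero(self):
        movie = np.full((3, 16, 16), 4.2)
        _, shifts = T.register_translation(movie)
        assert np.all(shifts == 0)


class TestRoiTrace:
    def test_uniform_frames_give_constant_trace(self):
        movie = np.full((5, 40, 40), 3.0)
        tr = T.roi_trace(movie, center=(1.0, 1.0), diameter=0.9, pixel_size=0.05)
        np.testing.assert_allclose(tr, 3.0)

    def test_centered_roi_brighter_than_displaced(self):
        yy, xx = np.mgrid[:60, :60]
        frame = np.exp(-((yy - 30) ** 2 + (xx - 30) ** 2) / (2 * 4.0**2))
        movie = frame[None]
        px = 0.1
        on = T.roi_trace(movie, (30 * px, 30 * px), diameter=1.0, pixel_size=px)
        off = T.roi_trace(movie, (30 * px, 50 * px), diameter=1.0, pixel_size=px)
        assert on[0] > off[0]

    def test_subpixel_diameter_rejected(self):
        movie = np.zeros((2, 20, 20))
        with pytest.raises(ValueError, match="smaller than one pixel"):
            T.roi_trace(movie, (0.5, 0.5), diameter=0.01, pixel_size=0.05)

    def test_roi_outside_bounds_rejected(self):
        movie = np.zeros((2, 20, 20))
        with pytest.raises(ValueError, match="outside"):
            T.roi_trace(movie, (0.0, 0.0), diameter=5.0, pixel_size=0.05)


class TestEvokedDff:
    def test_boundary_peak_not_active(self):
        """Peak dF/F0 exactly at the 0.25 threshold is classified inactive."""
        values = np.full(100, 100.0)
        values[60] = 125.0
        ts = T.TraceSet(values, frame_rate=10.0, channel="GCaMP6sCAAX")
        res = T.evoked_dff(ts, (0.0, 5.0))
        assert res.peak[0] == pytest.approx(0.25)
        assert not res.active[0]
        assert res.threshold_used == 0.25

    def test_mito_channel_threshold(self):
        values = np.full(100, 100.0)
        values[60] = 110.0
        ts = T.TraceSet(values, frame_rate=10.0, channel="MitoGCaMP3")
        res = T.evoked_dff(ts, (0.0, 5.0))
        assert res.threshold_used == 0.05
        assert res.active[0]

    @given(gain=st.floats(0.1, 50.0))
    def test_gain_invariance(self, gain):
        rng = np.random.default_rng(3)
        values = 100.0 + rng.random(200) * 20
        a = T.evoked_dff(T.TraceSet(values, frame_rate=10.0), (0.0, 5.0))
        b = T.evoked_dff(T.TraceSet(values * gain, frame_rate=10.0), (0.0, 5.0))
        np.testing.assert_allclose(a.dff, b.dff, atol=1e-9)

    def test_simulated_plateau_recovered(self):
        spec = S.TraceSimSpec(
            noise_sd=0.0, kinetics={"cyto": S.ChannelKinetics(0.06, 3.0, plateau=0.5)}
        )
        sets, _ = S.simulate_evoked_traces(spec)
        res = T.evoked_dff(sets["cyto"], (0.0, 10.0))
        assert res.peak[0] == pytest.approx(0.5, rel=0.01)
        assert res.active[0]

    def test_nonpositive_baseline_rejected(self):
        ts = T.TraceSet(np.zeros(50), frame_rate=10.0)
        with pytest.raises(ValueError, match="F0"):
            T.evoked_dff(ts, (0.0, 2.0))


class TestDffMap:
    def test_static_movie_zero_map(self):
        movie = np.full((20, 8, 8), 5.0)
        maps, scale = T.dff_map(movie, prestim_frames=5, bin_frames=1)
        np.testing.assert_allclose(maps, 0.0)

    def test_single_pixel_step_localized(self):
        movie = np.zeros((20, 8, 8)) + 1.0
        movie[10:, 3, 4] += 10.0
        maps, _ = T.dff_map(movie, prestim_frames=5, bin_frames=15)
        assert maps.shape == (1, 8, 8)
        assert maps[0, 3, 4] == pytest.approx(10.0 * 10 / 15)
        assert np.count_nonzero(maps[0]) == 1

    def test_identity_binning_preserves_frame_count(self):
        movie = np.random.default_rng(0).random((30, 6, 6))
        maps, _ = T.dff_map(movie, prestim_frames=10, bin_frames=1)
        assert maps.shape[0] == 20

    def test_oversized_bin_rejected(self):
        with pytest.raises(ValueError):
            T.dff_map(np.zeros((10, 4, 4)), prestim_frames=5, bin_frames=6)


class TestBleachCorrect:
    def test_pure_exponential_flattened(self):
        t = np.arange(300) * 3.0
        trace = 100.0 * np.exp(-t / 600.0)
        corrected, info = T.bleach_correct(trace, frame_rate=1 / 3)
        assert info["ok"]
        assert np.ptp(corrected) / corrected.mean() < 0.02
        assert info["tau"] == pytest.approx(600.0, rel=0.05)

    def test_flat_trace_nearly_unchanged(self):
        trace = np.full(100, 50.0)
        corrected, _ = T.bleach_correct(trace, frame_rate=1.0)
        np.testing.assert_allclose(corrected, trace, rtol=0.01)

    def test_events_preserved_while_baseline_flattened(self):
        spec = cyto_only(event_times=(150.0, 450.0, 750.0), amplitude_mean=1.0,
                         amplitude_sd=0.0, bleach_tau=600.0)
        sets, _ = S.simulate_spontaneous_traces(spec)
        corrected, info = T.bleach_correct(sets["cyto"].values[0], frame_rate=1 / 3)
        assert info["ok"]
        baseline = np.percentile(corrected, 15)
        drift = abs(corrected[:20].mean() - corrected[-20:].mean()) / baseline
        assert drift < 0.02
        stats = T.spontaneous_stats(corrected, 1 / 3)
        # the sampled kernel peak of each planted event, against ground truth 1.0
        peaks = np.sort(stats.dff[stats.dff > 0])[-3:]
        kernel_peak = S.event_kernel(
            np.arange(0, 6, 3.0) + (3.0 - 150.0 % 3.0) % 3.0, spec.kinetics["cyto"]
        ).max()
        np.testing.assert_allclose(peaks, kernel_peak, rtol=0.10)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            T.bleach_correct(np.ones(10))


class TestSpontaneousStats:
    def test_all_subthreshold_gives_zero(self):
        trace = np.full(300, 100.0)
        trace[::2] = 105.0  # dff 0.05 at most, below the 10% floor
        stats = T.spontaneous_stats(trace, 1 / 3)
        assert stats.magnitude == 0.0
        assert stats.frequency == 0.0

    def test_magnitude_is_suprathreshold_sum_over_frames(self):
        trace = np.full(300, 100.0)
        trace[100] = 400.0  # single event, dff = 3.0
        stats = T.spontaneous_stats(trace, 1 / 3)
        assert stats.f0 == pytest.approx(100.0)
        assert stats.magnitude == pytest.approx(3.0 / 300)
        assert stats.frequency == pytest.approx(1 / 900)

    def test_planted_events_frequency_exact(self):
        times = tuple(50.0 + 90.0 * k for k in range(9))
        spec = cyto_only(event_times=times, amplitude_mean=1.0, amplitude_sd=0.0)
        sets, _ = S.simulate_spontaneous_traces(spec)
        stats = T.spontaneous_stats(sets["cyto"].values[0], 1 / 3)
        assert stats.frequency == pytest.approx(0.01)

    def test_magnitude_monotone_in_amplitude(self):
        def mag(amp):
            spec = cyto_only(event_times=(150.0, 450.0), amplitude_mean=amp,
                             amplitude_sd=0.0)
            sets, _ = S.simulate_spontaneous_traces(spec)
            return T.spontaneous_stats(sets["cyto"].values[0], 1 / 3).magnitude

        mags = [mag(a) for a in (0.5, 1.0, 2.0)]
        assert mags[0] <= mags[1] <= mags[2]

    def test_mean_lowest_baseline_mode(self):
        rng = np.random.default_rng(5)
        trace = 100.0 + rng.random(300)
        a = T.spontaneous_stats(trace, 1 / 3, baseline_mode="percentile")
        b = T.spontaneous_stats(trace, 1 / 3, baseline_mode="mean_lowest")
        assert b.f0 < a.f0  # averaging the lowest 15% sits below the percentile value


class TestPearsonMatrix:
    def test_self_correlation_and_negation(self):
        rng = np.random.default_rng(2)
        v = rng.random((1, 100))
        ts = T.TraceSet(v, frame_rate=1.0)
        neg = T.TraceSet(-v, frame_rate=1.0)
        assert T.pearson_matrix(ts, ts)[0, 0] == pytest.approx(1.0)
        assert T.pearson_matrix(ts, neg)[0, 0] == pytest.approx(-1.0)

    def test_zero_variance_flagged_nan(self):
        a = T.TraceSet(np.ones((1, 50)), frame_rate=1.0)
        b = T.TraceSet(np.random.default_rng(0).random((1, 50)), frame_rate=1.0)
        assert np.isnan(T.pearson_matrix(a, b)[0, 0])

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(4)
        ts = T.TraceSet(rng.random((5, 80)), frame_rate=1.0)
        r = T.pearson_matrix(ts, ts)
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        assert np.all(r >= -1.0) and np.all(r <= 1.0)

    def test_coupled_channels_correlate(self):
        kin = {"a": S.ChannelKinetics(0.06, 4.0), "b": S.ChannelKinetics(0.06, 4.0)}
        spec = S.TraceSimSpec(
            frame_rate=0.2, duration=900.0, stimulus_windows=(), event_rate=0.02,
            coupling=1.0, noise_sd=0.0, n_cells=5, kinetics=kin, seed=7,
        )
        sets, _ = S.simulate_spontaneous_traces(spec)
        r = T.pearson_matrix(sets["a"], sets["b"])
        assert np.all(np.diag(r) > 0.95)


class TestMockNormalization:
    def test_bleach_matched_treated_is_one(self):
        mock = [T.BaselinePair(100.0, 80.0, treated=False)] * 3
        treated = [T.BaselinePair(100.0, 80.0)]
        np.testing.assert_allclose(T.normalize_to_mock(treated, mock), [1.0])

    def test_half_effect(self):
        mock = [T.BaselinePair(100.0, 80.0, treated=False)]
        treated = [T.BaselinePair(100.0, 40.0)]
        np.testing.assert_allclose(T.normalize_to_mock(treated, mock), [0.5])

    def test_self_normalization_means_one(self):
        pairs = [T.BaselinePair(100.0, v, treated=False) for v in (70.0, 80.0, 90.0)]
        assert T.normalize_to_mock(pairs, pairs).mean() == pytest.approx(1.0)

    def test_empty_mock_rejected(self):
        with pytest.raises(ValueError):
            T.normalize_to_mock([T.BaselinePair(1.0, 1.0)], [])


class TestAverageReplicateStacks:
    @pytest.mark.parametrize(
        "vals,expected", [([10, 10, 10, 10], 10.0), ([8, 12, 9, 11], 10.0), ([7.5], 7.5)]
    )
    def test_mean(self, vals, expected):
        assert T.average_replicate_stacks(vals) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            T.average_replicate_stacks([])


class TestFit4PL:
    def test_noise_free_round_trip(self):
        df = S.simulate_dose_response(1.37, 1.0, 0.0, 1.0, [0, 0.5, 2, 5, 10])
        fit = T.fit_4pl(df.dose_uM.to_numpy(), df.response.to_numpy())
        assert fit.ok
        assert fit.ic50 == pytest.approx(1.37, rel=0.01)
        assert fit.hill == pytest.approx(1.0, rel=0.05)

    def test_flat_responses_flagged_degenerate(self):
        fit = T.fit_4pl(np.array([0, 0.5, 2, 5, 10]), np.full(5, 0.7))
        assert not fit.ok
        assert "degenerate" in fit.message

    def test_median_recovery_under_noise(self):
        recovered = []
        for seed in range(1, 21):
            df = S.simulate_dose_response(
                1.37, 1.0, 0.0, 1.0, [0, 0.5, 2, 5, 10], noise_sd=0.02, seed=seed
            )
            fit = T.fit_4pl(df.dose_uM.to_numpy(), df.response.to_numpy())
            assert fit.ok
            recovered.append(fit.ic50)
        assert np.median(recovered) == pytest.approx(1.37, rel=0.10)

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError):
            T.fit_4pl(np.array([0, 1, 2]), np.array([1.0, 0.5, 0.2]))
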