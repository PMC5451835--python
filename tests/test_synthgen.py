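"""Generator-level checks: timing mixture, degradation models, imagery, EMG."""

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings, strategies as st

from ussync import synthgen as sg
from ussync.datatypes import TimestampSeries


class TestTrueFrameTimes:
    def test_degenerate_mixture_gives_constant_ifi(self):
        model = sg.TimingModel(nominal_rate=82.0, mode_rates=(82.0, 62.5),
                               mode_weight=1.0, quantization=0.0)
        series, ifis = sg.generate_true_frame_times(model, 1.0, seed=0)
        assert series.times[0] == 0.0
        assert np.allclose(ifis, 1.0 / 82.0)

    def test_times_quantized_monotone_and_bounded(self):
        model = sg.TimingModel()
        series, ifis = sg.generate_true_frame_times(model, 5.0, seed=7)
        assert np.all(np.diff(series.times) > 0)
        assert series.times[-1] <= 5.0
        grid = np.round(series.times / model.quantization) * model.quantization
        assert np.allclose(series.times, grid, atol=1e-12)

    def test_dominant_mode_fraction_matches_mixture_weight(self):
        """82 fps preset over a full-length trial recovers the 0.9272 weight."""
        model = sg.PRESETS["telemed82"]
        series, ifis = sg.generate_true_frame_times(model, 217.0, seed=11)
        dominant = np.abs(ifis - 1.0 / 83.5) < np.abs(ifis - 1.0 / 62.5)
        frac = dominant.mean()
        n = len(ifis)
        sd = np.sqrt(0.9272 * (1 - 0.9272) / n)
        assert abs(frac - 0.9272) < 3 * sd

    def test_mixture_mean_matches_closed_form(self):
        model = sg.TimingModel(nominal_rate=75.0, mode_rates=(100.0, 50.0),
                               mode_weight=0.5, quantization=0.0)
        # closed-form mixture mean: 0.5/100 + 0.5/50 = 0.015 s
        series, ifis = sg.generate_true_frame_times(model, 1.5e4, seed=2)
        n = len(ifis)
        sd = 0.5 * abs(1 / 100 - 1 / 50)  # two-point SD at w = 0.5
        assert n > 9e5
        assert abs(ifis.mean() - 0.015) < 3 * sd / np.sqrt(n)

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            sg.generate_true_frame_times(sg.TimingModel(), 0.0, seed=0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(w=st.floats(0.05, 0.95), seed=st.integers(0, 2**20))
    def test_mixture_fraction_recovery_property(self, w, seed):
        model = sg.TimingModel(nominal_rate=82.0, mode_rates=(83.5, 62.5),
                               mode_weight=w, quantization=0.0)
        series, ifis = sg.generate_true_frame_times(model, 30.0, seed=seed)
        n = len(ifis)
        assert n >= 1000
        frac = (np.abs(ifis - 1 / 83.5) < np.abs(ifis - 1 / 62.5)).mean()
        assert abs(frac - w) <= 4 * np.sqrt(w * (1 - w) / n) + 1e-12


class TestSoftwareDegradation:
    def test_identity_when_no_drops_or_jitter(self):
        model = sg.TimingModel(jitter_sd=0.0, drop_prob=0.0)
        series, _ = sg.generate_true_frame_times(model, 2.0, seed=0)
        sw, dropped = sg.degrade_to_software_timestamps(series, model, seed=1)
        assert len(dropped) == 0
        assert np.array_equal(sw.times, series.times)
        assert sw.source == "software"

    def test_forced_drop_telescopes_ifis(self):
        model = sg.TimingModel(jitter_sd=0.0)
        series, ifis = sg.generate_true_frame_times(model, 2.0, seed=0)
        k = 40
        sw, dropped = sg.degrade_to_software_timestamps(
            series, model, seed=1, drop_indices=np.array([k])
        )
        sw_ifis = np.diff(sw.times)
        assert np.isclose(sw_ifis[k - 1], ifis[k - 1] + ifis[k])
        assert np.array_equal(dropped, [k])

    def test_drop_count_binomial(self):
        model = sg.TimingModel(mode_rates=(100.0, 100.0), mode_weight=1.0,
                               nominal_rate=100.0, drop_prob=0.1,
                               quantization=0.0)
        series, _ = sg.generate_true_frame_times(model, 100.0, seed=4)
        n = len(series)
        assert n > 9000
        _, dropped = sg.degrade_to_software_timestamps(series, model, seed=4)
        sd = np.sqrt(n * 0.1 * 0.9)
        assert abs(len(dropped) - 0.1 * n) < 3 * sd

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(p=st.floats(0.0, 0.3), seed=st.integers(0, 2**20))
    def test_drop_bookkeeping_invariant(self, p, seed):
        """|software| + |dropped| = |true|, always."""
        model = sg.TimingModel(drop_prob=p, jitter_sd=1e-4)
        series, _ = sg.generate_true_frame_times(model, 3.0, seed=seed)
        sw, dropped = sg.degrade_to_software_timestamps(series, model, seed=seed)
        assert len(sw) + len(dropped) == len(series)
        assert np.all(np.diff(sw.times) >= 0)


class TestHardwareTimestamps:
    def test_zero_quantization_is_identity(self):
        series = TimestampSeries(np.array([0.0, 0.0123, 0.0246]))
        hw = sg.hardware_timestamps(series, quantization=0.0)
        assert np.array_equal(hw.times, series.times)

    def test_constant_ifi_variance_below_measurement_accuracy(self):
        t = np.arange(1000) * (1.0 / 150.7)
        hw = sg.hardware_timestamps(TimestampSeries(t), quantization=25e-6)
        assert np.var(np.diff(hw.times)) <= (25e-6) ** 2

    def test_rounding_bound(self, rng):
        t = np.sort(rng.uniform(0, 10, size=500))
        q = 25e-6
        hw = sg.hardware_timestamps(TimestampSeries(t), quantization=q)
        assert np.max(np.abs(hw.times - t)) <= q / 2 + 1e-15


class TestSpeckleSequence:
    def test_zero_displacement_means_noise_only_differences(self):
        model = sg.TimingModel()
        series, _ = sg.generate_true_frame_times(model, 0.3, seed=0)
        schedule = sg.TwitchSchedule(onsets=np.array([0.1]),
                                     peak_displacement=(0.0, 0.0),
                                     region_centre=(64.0, 64.0))
        images, truth = sg.generate_speckle_sequence(
            series, schedule, noise_sd=0.0, seed=0
        )
        assert np.all(truth == 0.0)
        assert np.array_equal(images.frames[0], images.frames[-1])

    def test_warp_at_profile_peak_matches_analytic_formula(self):
        schedule = sg.TwitchSchedule(onsets=np.array([1.0]),
                                     peak_displacement=(3.0, 0.0),
                                     region_centre=(64.0, 64.0))
        t_peak = 1.0 + schedule.latency + schedule.rise_time
        dx, dy = schedule.displacement_at(64.0, 64.0, t_peak)
        assert np.isclose(dx, 3.0)
        assert np.isclose(dy, 0.0)
        # off-centre, the Gaussian window applies exactly
        off = 64.0 + schedule.region_sd
        dx_off, _ = schedule.displacement_at(off, 64.0, t_peak)
        assert np.isclose(dx_off, 3.0 * np.exp(-0.5))

    def test_default_schedule_has_eight_twitches_in_40s(self):
        schedule = sg.TwitchSchedule()
        assert len(schedule.onsets) == 8
        assert np.allclose(schedule.onsets, np.arange(5.0, 41.0, 5.0))

    def test_warp_consistency_with_ground_truth(self):
        """Noise-free transition truth equals the analytic warp difference."""
        model = sg.TimingModel()
        series, _ = sg.generate_true_frame_times(model, 2.0, seed=1)
        schedule = sg.TwitchSchedule(onsets=np.array([0.5]),
                                     region_centre=(64.0, 64.0))
        _, truth = sg.generate_speckle_sequence(series, schedule,
                                                noise_sd=0.0, seed=1)
        t = series.times
        dx, _ = schedule.displacement_at(64.0, 64.0, t)
        assert np.allclose(truth[:, 0], np.diff(dx))

    def test_too_small_image_rejected(self):
        series = TimestampSeries(np.array([0.0, 0.01]))
        with pytest.raises(ValueError):
            sg.generate_speckle_sequence(series, sg.TwitchSchedule(),
                                         image_size=(32, 32))


class TestEMG:
    def test_sample_count_and_noise_sd(self):
        model = sg.EMGModel(noise_sd=0.05)
        trace = sg.generate_emg(np.empty(0), model, duration=40.0, seed=0)
        assert len(trace) == 80_000
        se = 0.05 / np.sqrt(2 * (len(trace) - 1))
        assert abs(np.std(trace.samples) - 0.05) < 3 * se

    def test_mwave_half_amplitude_crossing(self):
        """First sample above half the M-wave amplitude after the artifact
        occurs where direct evaluation of the damped sinusoid predicts."""
        model = sg.EMGModel(noise_sd=0.0, mwave_latency=0.008)
        onset = 5.0
        trace = sg.generate_emg(np.array([onset]), model, duration=10.0, seed=0)
        t = trace.times
        after = t > onset + model.artifact_width
        crossing = t[after][trace.samples[after] > model.mwave_amplitude / 2][0]
        # oracle: evaluate the damped sinusoid on the sample grid directly
        tau = t - onset - model.mwave_latency
        oracle_vals = model.mwave(tau)
        oracle_crossing = t[oracle_vals > model.mwave_amplitude / 2][0]
        assert crossing == oracle_crossing
        assert abs(crossing - 5.008) <= 1.0 / model.fs + 1e-12


@pytest.fixture(scope="module")
def dataset():
    return sg.generate_dataset(
        timing=sg.PRESETS["sonix-drop"],
        schedule=sg.TwitchSchedule(onsets=np.array([0.5]),
                                   region_centre=(32.0, 32.0),
                                   region_sd=10.0),
        duration=1.2,
        image_size=(64, 64),
        seed=9,
    )


class TestWriteDataset:
    def test_round_trip(self, dataset, tmp_path):
        from ussync.ifi_analysis import read_timestamps

        paths = sg.write_dataset(tmp_path / "d", dataset)
        frames = tifffile.imread(paths["images"])
        assert np.array_equal(frames, dataset.images.frames)
        meta = read_timestamps(paths["timestamps_metadata"])
        assert np.array_equal(meta.times, dataset.metadata_times.times)
        assert meta.quantization == dataset.metadata_times.quantization
        assert meta.source == "metadata"
        sw = read_timestamps(paths["timestamps_software"])
        assert len(sw) + len(dataset.dropped_indices) == len(meta)

    def test_same_seed_byte_identical(self, dataset, tmp_path):
        ds2 = sg.generate_dataset(
            timing=sg.PRESETS["sonix-drop"],
            schedule=sg.TwitchSchedule(onsets=np.array([0.5]),
                                       region_centre=(32.0, 32.0),
                                       region_sd=10.0),
            duration=1.2,
            image_size=(64, 64),
            seed=9,
        )
        p1 = sg.write_dataset(tmp_path / "a", dataset)
        p2 = sg.write_dataset(tmp_path / "b", ds2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seed_changes_frames(self, dataset):
        other = sg.generate_dataset(
            timing=sg.PRESETS["sonix-drop"],
            schedule=sg.TwitchSchedule(onsets=np.array([0.5]),
                                       region_centre=(32.0, 32.0),
                                       region_sd=10.0),
            duration=1.2,
            image_size=(64, 64),
            seed=10,
        )
        assert not np.array_equal(other.images.frames, dataset.images.frames)
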