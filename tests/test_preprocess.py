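"""Filtering, downsampling, segmentation, labelling, standardization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from bafawubu import preprocess as pp
from bafawubu import simulate as sim
from bafawubu.exceptions import InsufficientDataError
from bafawubu.movements import TRANSITION_LABEL


def _sine_stream(freq, rate, duration=10.0, amp=1.0):
    t = np.arange(int(duration * rate)) / rate
    samples = np.zeros((len(t), 6))
    samples[:, 2] = amp * np.sin(2 * np.pi * freq * t)
    return sim.ImuStream(rate_hz=rate, samples=samples)


class TestLowPass:
    def test_dc_gain_is_one(self):
        stream = sim.ImuStream(200.0, np.tile([0, 0, 1.0, 0, 0, 0], (2000, 1)))
        out = pp.low_pass(stream)
        assert np.allclose(out.samples, stream.samples, atol=1e-6)

    @pytest.mark.parametrize("freq,bound,side", [
        (2.0, 0.99, "ge"),    # passband: tai chi tempo survives
        (25.0, 0.10, "le"),   # stopband: interference is removed
    ])
    def test_magnitude_matches_butterworth_oracle(self, freq, bound, side):
        """Measured sinusoid gain agrees with the analytic 4th-order
        Butterworth magnitude response (squared: forward-backward pass)."""
        stream = _sine_stream(freq, 200.0)
        out = pp.low_pass(stream).samples[:, 2]
        interior = out[400:-400]
        measured = interior.max() - interior.min()
        sos = sps.butter(4, 5.0, btype="low", fs=200.0, output="sos")
        _, h = sps.sosfreqz(sos, worN=[freq], fs=200.0)
        expected = 2.0 * np.abs(h[0]) ** 2  # peak-to-peak, two passes
        assert measured == pytest.approx(expected, rel=0.02, abs=1e-6)
        if side == "ge":
            assert measured / 2.0 >= bound
        else:
            assert measured / 2.0 <= bound

    def test_zero_phase_commutes_with_time_reversal(self):
        # zero-phase filtering commutes with time reversal away from the
        # edge-padding transients
        rng = np.random.default_rng(0)
        stream = sim.ImuStream(200.0, rng.standard_normal((1500, 6)))
        fwd = pp.low_pass(stream).samples
        rev = pp.low_pass(sim.ImuStream(200.0,
                                        stream.samples[::-1].copy())).samples
        assert np.allclose(fwd[300:-300], rev[::-1][300:-300], atol=1e-6)

    def test_cutoff_above_nyquist_rejected(self):
        stream = _sine_stream(1.0, 8.0, duration=30.0)
        with pytest.raises(ValueError):
            pp.low_pass(stream)


class TestResample:
    def test_integer_decimation(self):
        stream = _sine_stream(2.0, 200.0, duration=10.0)
        out = pp.resample_to(stream, 50.0)
        assert len(out) == 500 and out.rate_hz == 50.0
        assert np.array_equal(out.samples, stream.samples[::4])

    def test_identity_at_target_rate(self):
        stream = _sine_stream(2.0, 50.0, duration=10.0)
        out = pp.resample_to(stream, 50.0)
        assert np.array_equal(out.samples, stream.samples)

    def test_rational_resampling_against_analytic_sinusoid(self):
        # 80 Hz -> 50 Hz is a 5:8 polyphase resample; the output must be the
        # same 2 Hz sinusoid evaluated on the 50 Hz grid
        stream = _sine_stream(2.0, 80.0, duration=10.0)
        out = pp.resample_to(stream, 50.0)
        assert len(out) == 500
        t = np.arange(500) / 50.0
        expected = np.sin(2 * np.pi * 2.0 * t)
        assert np.allclose(out.samples[100:-100, 2], expected[100:-100],
                           atol=5e-3)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            pp.resample_to(_sine_stream(1.0, 50.0), 100.0)

    def test_labels_carried_by_nearest_sample(self):
        samples = np.zeros((400, 6))
        labels = np.asarray(["WOF"] * 200 + ["PB"] * 200, dtype=object)
        stream = sim.ImuStream(200.0, samples, labels)
        out = pp.resample_to(stream, 50.0)
        assert np.sum(out.labels == "WOF") == 50
        assert np.sum(out.labels == "PB") == 50


class TestSegment:
    @pytest.mark.parametrize("duration,expected", [(60.0, 59), (2.0, 1)])
    def test_window_counts(self, duration, expected):
        stream = _sine_stream(1.0, 50.0, duration=duration)
        dataset = pp.segment(stream)
        assert len(dataset) == expected
        assert dataset.windows.shape[1:] == (100, 6)

    def test_too_short_stream(self):
        stream = _sine_stream(1.0, 50.0, duration=1.5)
        with pytest.raises(InsufficientDataError):
            pp.segment(stream)

    def test_windows_are_contiguous_slices(self):
        stream = _sine_stream(0.7, 50.0, duration=5.0)
        dataset = pp.segment(stream)
        for i in range(len(dataset)):
            assert np.array_equal(dataset.windows[i],
                                  stream.samples[i * 50: i * 50 + 100])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(n=st.integers(10, 3000), length=st.integers(2, 200),
           overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75]))
    def test_count_formula_over_random_sizes(self, n, length, overlap):
        seg = pp.WindowSegmenter(length_s=length, overlap_frac=overlap,
                                 rate_hz=1.0)
        hop = max(int(round(length * (1 - overlap))), 1)
        if n < length:
            with pytest.raises(InsufficientDataError):
                seg.n_windows(n)
        else:
            windows = seg.transform(np.arange(n, dtype=float)[:, None])
            assert len(windows) == (n - length) // hop + 1

    def test_half_window_concatenation_reconstructs_interior(self):
        # with 50% overlap, the first halves of consecutive windows tile
        # the stream from its start
        rng = np.random.default_rng(3)
        stream = sim.ImuStream(50.0, rng.standard_normal((500, 6)))
        dataset = pp.segment(stream)
        rebuilt = np.concatenate([w[:50] for w in dataset.windows])
        assert np.array_equal(rebuilt, stream.samples[: len(rebuilt)])


class TestLabelWindows:
    def _dataset(self, n_windows):
        return pp.WindowedDataset(np.zeros((n_windows, 100, 6)),
                                  np.full(n_windows, "", dtype=object))

    def test_majority_and_pure_windows(self):
        labels = np.asarray(["WOF"] * 110 + ["LF"] * 40, dtype=object)
        out = pp.label_windows(self._dataset(2), labels)
        # window 0 pure WOF; window 1 has 60 WOF / 40 LF
        assert list(out.labels) == ["WOF", "WOF"]

    def test_transition_samples_excluded_and_pure_transition_dropped(self):
        labels = np.asarray([TRANSITION_LABEL] * 100 + ["PB"] * 100,
                            dtype=object)
        out = pp.label_windows(self._dataset(3), labels)
        # window 0 transition-only (dropped); windows 1-2 majority PB
        assert list(out.labels) == ["PB", "PB"]
        assert len(out) == 2

    def test_tie_broken_by_centre_sample(self):
        labels = np.asarray(["WOF"] * 50 + ["LF"] * 100, dtype=object)
        out = pp.label_windows(self._dataset(1), labels[:100])
        # 50/50 tie; centre sample (index 50) is LF
        assert list(out.labels) == ["LF"]

    def test_misaligned_labels_rejected(self):
        with pytest.raises(ValueError):
            pp.label_windows(self._dataset(2), np.asarray(["WOF"] * 100))


class TestStandardize:
    def test_self_statistics_zero_mean_unit_sd(self, small_dataset):
        out = pp.standardize(small_dataset)
        flat = out.windows.reshape(-1, 6)
        assert np.all(np.abs(flat.mean(axis=0)) < 1e-9)
        assert np.allclose(flat.std(axis=0), 1.0)
        assert out.channel_stats is not None

    def test_constant_channel_floored_with_warning(self):
        windows = np.zeros((4, 100, 6))
        dataset = pp.WindowedDataset(windows, np.full(4, "WOF", dtype=object))
        with pytest.warns(RuntimeWarning):
            out = pp.standardize(dataset)
        assert np.all(np.isfinite(out.windows))

    def test_train_stats_on_shifted_copy(self):
        rng = np.random.default_rng(1)
        windows = rng.standard_normal((20, 100, 6))
        dataset = pp.WindowedDataset(windows, np.full(20, "LF", dtype=object))
        fitted = pp.standardize(dataset)
        shift = 2.5
        shifted = pp.WindowedDataset(windows + shift, dataset.labels)
        out = pp.standardize(shifted, stats=fitted.channel_stats)
        expected = shift / fitted.channel_stats.sd_
        mean = out.windows.reshape(-1, 6).mean(axis=0)
        assert np.allclose(mean, expected, atol=1e-9)


def test_windowed_dataset_save_load_round_trip(tmp_path, small_dataset):
    subset = small_dataset.subset(np.arange(10))
    subset = pp.standardize(subset)
    subset.save(tmp_path / "ds")
    back = pp.WindowedDataset.load(tmp_path / "ds")
    assert np.array_equal(back.windows, subset.windows)
    assert np.array_equal(back.labels, subset.labels)
    assert np.allclose(back.channel_stats.mean_, subset.channel_stats.mean_)
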