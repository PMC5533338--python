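"""Spectral front end: hop quantization, band bins, frames, chunking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sylldet as s
from sylldet.frontend import power_spectrum


class TestFrameIntervalQuantization:
    @pytest.mark.parametrize(
        "rate,requested_ms,hop,effective_ms",
        [
            (44100, 1.0, 44, 44 / 44.1),
            (44100, 1.5, 66, 66 / 44.1),
            (40000, 1.0, 40, 1.0),
        ],
    )
    def test_hop_rounded_to_nearest_sample(self, rate, requested_ms, hop,
                                           effective_ms):
        cfg = s.resolve_frame_config(
            requested_interval_ms=requested_ms, sample_rate=rate
        )
        assert cfg.hop == hop
        assert cfg.effective_interval_ms == pytest.approx(effective_ms,
                                                          abs=1e-12)

    def test_effective_interval_times_rate_is_integer(self):
        for req in (0.5, 0.9977, 1.3, 2.0, 4.0):
            cfg = s.resolve_frame_config(requested_interval_ms=req)
            n = cfg.effective_interval_ms * cfg.sample_rate / 1000.0
            assert n == pytest.approx(round(n), abs=1e-9)

    def test_window_frame_count(self):
        cfg = s.resolve_frame_config()
        assert cfg.n_frames == 33  # round(50 / 1.4966)

    def test_sub_sample_interval_rejected(self):
        with pytest.raises(ValueError):
            s.resolve_frame_config(requested_interval_ms=0.005)

    def test_hop_beyond_window_rejected(self):
        with pytest.raises(ValueError):
            s.resolve_frame_config(fft_size=64, requested_interval_ms=10.0)


class TestBandBins:
    def test_default_band_enumeration(self):
        # independent enumeration of bin centers k * 44100/256
        expected = [
            k for k in range(129) if 1000.0 <= k * 44100 / 256 <= 8000.0
        ]
        bins = s.band_bins(256, 44100, (1000.0, 8000.0))
        assert list(bins) == expected
        assert len(bins) == 41
        assert bins[0] == 6 and bins[-1] == 46

    def test_full_band_keeps_all_one_sided_bins(self):
        assert len(s.band_bins(256, 44100, (0.0, 22050.0))) == 129

    def test_degenerate_band_at_bin_center(self):
        f = 10 * 44100 / 256
        assert list(s.band_bins(256, 44100, (f, f))) == [10]

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            s.band_bins(256, 44100, (1000.0, 1001.0))


class TestComputeFrame:
    def test_silence_gives_zero_power(self, default_config):
        p = s.compute_frame(np.zeros(256), default_config)
        assert np.all(p == 0.0)

    def test_sinusoid_peaks_at_its_bin(self, default_config):
        # closed form: Hamming-windowed sinusoid at a bin center has its
        # spectral maximum at that bin
        for k in (10, 25, 40):
            f = k * 44100 / 256
            t = np.arange(256) / 44100
            p = s.compute_frame(np.sin(2 * np.pi * f * t), default_config)
            assert default_config.bins[np.argmax(p)] == k

    def test_amplitude_scales_quadratically(self, default_config):
        rng = np.random.default_rng(0)
        x = rng.normal(size=256)
        p1 = s.compute_frame(x, default_config)
        p3 = s.compute_frame(3.0 * x, default_config)
        np.testing.assert_allclose(p3, 9.0 * p1, rtol=1e-12)

    def test_wrong_window_length_rejected(self, default_config):
        with pytest.raises(ValueError):
            s.compute_frame(np.zeros(255), default_config)

    def test_power_bounded_by_windowed_energy(self, default_config):
        # Parseval: the full two-sided power sums to N * windowed energy,
        # so the one-sided band-limited sum can never exceed it
        rng = np.random.default_rng(1)
        x = rng.normal(size=256)
        full = power_spectrum(x, 256)
        energy = np.sum((np.hamming(256) * x) ** 2)
        assert full.sum() <= 256 * energy * (1 + 1e-12)
        assert s.compute_frame(x, default_config).sum() <= full.sum()


class TestStreaming:
    def test_single_window_yields_one_frame(self, default_config):
        frames = s.stream_frames(np.ones(256), default_config)
        assert len(frames) == 1
        assert frames[0].end_sample == 256

    def test_frame_count_matches_hops(self, default_config):
        n = 256 + 3 * default_config.hop
        frames = s.stream_frames(np.ones(n), default_config)
        assert len(frames) == 4
        assert [f.end_sample for f in frames] == [
            256 + k * default_config.hop for k in range(4)
        ]

    def test_no_frame_before_first_window_fills(self, default_config):
        streamer = s.FrameStreamer(default_config)
        assert streamer.feed(np.ones(255)) == []
        out = streamer.feed(np.ones(1))
        assert len(out) == 1

    @pytest.mark.parametrize("chunk", [1, 8, 32, 97, 256])
    def test_chunked_equals_whole(self, default_config, chunk):
        rng = np.random.default_rng(2)
        audio = rng.normal(size=2000)
        whole = s.stream_frames(audio, default_config)
        streamer = s.FrameStreamer(default_config)
        pieces = []
        for i in range(0, len(audio), chunk):
            pieces.extend(streamer.feed(audio[i : i + chunk]))
        assert len(pieces) == len(whole)
        for a, b in zip(pieces, whole):
            assert a.end_sample == b.end_sample
            np.testing.assert_array_equal(a.power, b.power)

    @given(st.lists(st.integers(min_value=1, max_value=300), min_size=1,
                    max_size=30))
    @settings(max_examples=25, deadline=None)
    def test_arbitrary_partitions_are_equivalent(self, sizes):
        cfg = s.resolve_frame_config()
        rng = np.random.default_rng(3)
        audio = rng.normal(size=sum(sizes))
        streamer = s.FrameStreamer(cfg)
        pieces = []
        pos = 0
        for n in sizes:
            pieces.extend(streamer.feed(audio[pos : pos + n]))
            pos += n
        if len(audio) >= cfg.fft_size:
            whole = s.stream_frames(audio, cfg)
        else:
            whole = []
            assert pieces == []
        for a, b in zip(pieces, whole):
            np.testing.assert_array_equal(a.power, b.power)
        assert len(pieces) == len(whole)

    def test_batch_matches_streaming_bitwise(self, default_config):
        rng = np.random.default_rng(4)
        audio = rng.normal(size=1500)
        batch = s.frame_powers(audio, default_config)
        streamed = s.stream_frames(audio, default_config)
        assert batch.shape[0] == len(streamed)
        for k, frame in enumerate(streamed):
            np.testing.assert_array_equal(batch[k], frame.power)
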