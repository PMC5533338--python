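"""Streaming detection: chunking invariance, de-bouncing, test-file I/O."""

import numpy as np
import pytest

import sylldet as s


def _stream(model, audio, chunk):
    det = s.StreamDetector(model)
    events = []
    for i in range(0, len(audio), chunk):
        events.extend(det.feed(audio[i : i + chunk]))
    return events


def _delta_stream(model, impulse_times_s, total_s, sample_rate=44100):
    """Silence with unit impulses; the δ-trained model triggers ~5 ms after
    each, provided they are spaced beyond the de-bounce interval."""
    audio = np.zeros(int(total_s * sample_rate))
    for t in impulse_times_s:
        audio[int(t * sample_rate)] = 1.0
    return audio


class TestStreamingDetection:
    def test_silence_produces_no_events(self, small_delta_model):
        audio = np.zeros(44100)
        assert _stream(small_delta_model, audio, 256) == []

    def test_impulse_triggers_once_near_target(self, small_delta_model):
        audio = _delta_stream(small_delta_model, [0.100], 0.3)
        events = _stream(small_delta_model, audio, 32)
        assert len(events) == 1
        e = events[0]
        assert e.syllable == 0
        assert e.output_value > small_delta_model.thresholds[0]
        # trigger ~5 ms (the trained offset) after the impulse
        assert 0.100 + 0.003 < e.trigger_time_s < 0.100 + 0.008

    def test_chunked_and_whole_feeds_agree_event_for_event(
        self, small_delta_model
    ):
        audio = _delta_stream(small_delta_model, [0.08, 0.35], 0.5)
        whole = _stream(small_delta_model, audio, len(audio))
        chunked = _stream(small_delta_model, audio, 8)
        assert whole == chunked
        assert len(whole) == 2

    def test_detect_file_equals_in_memory_feed(self, small_delta_model,
                                               tmp_path):
        audio = _delta_stream(small_delta_model, [0.1], 0.25)
        path = tmp_path / "stream.wav"
        s.write_wav(path, audio, 44100, dtype="float64")
        from_file = s.detect_file(small_delta_model, path, chunk_samples=32)
        in_memory = _stream(small_delta_model, audio, 32)
        assert from_file == in_memory

    def test_no_trigger_before_recognition_window_fills(
        self, small_delta_model
    ):
        cfg = small_delta_model.config
        audio = np.zeros(4 * cfg.fft_size)
        audio[0] = 1.0
        events = _stream(small_delta_model, audio, 16)
        min_sample = cfg.frame_end_sample(cfg.n_frames - 1)
        for e in events:
            assert e.trigger_sample >= min_sample


class TestDebounce:
    def test_excursions_50ms_apart_merge_to_one_event(self, small_delta_model):
        audio = _delta_stream(small_delta_model, [0.1, 0.15], 0.4)
        events = _stream(small_delta_model, audio, 64)
        assert len(events) == 1

    def test_excursions_150ms_apart_stay_separate(self, small_delta_model):
        audio = _delta_stream(small_delta_model, [0.1, 0.25], 0.5)
        events = _stream(small_delta_model, audio, 64)
        assert len(events) == 2

    def test_offline_ideal_path_matches_streaming_up_to_debounce(
        self, small_delta_model, small_delta_corpus
    ):
        from sylldet.evaluation import clip_outputs

        model = small_delta_model
        for clip in small_delta_corpus.songs[:5]:
            c = clip_outputs(model, clip)
            above = c.outputs[:, 0] > model.thresholds[0]
            # offline upward crossings (pre-debounce)
            crossings = np.flatnonzero(above & ~np.roll(above, 1))
            if above[0]:
                crossings = np.unique(np.concatenate([[0], crossings]))
            offline_times = c.times_ms[crossings]
            events = _stream(model, clip, 32)
            streamed_times = np.array(
                [e.trigger_time_s * 1000.0 for e in events]
            )
            # every streamed event is an offline crossing; extra offline
            # crossings may only have been suppressed by the 100 ms debounce
            for t in streamed_times:
                assert np.min(np.abs(offline_times - t)) < 1e-9
            kept = [offline_times[0]]
            for t in offline_times[1:]:
                if t - kept[-1] >= model.debounce_ms:
                    kept.append(t)
            np.testing.assert_allclose(streamed_times, kept, atol=1e-9)


class TestGroundTruthTestFile:
    def test_right_channel_impulse_count_and_positions(
        self, small_delta_corpus, tmp_path
    ):
        path = tmp_path / "test.wav"
        written = s.write_test_file(small_delta_corpus, path)
        left, impulses, rate = s.read_test_file(path)
        assert rate == small_delta_corpus.sample_rate
        assert len(impulses) == len(small_delta_corpus.songs)
        np.testing.assert_array_equal(impulses, written)
        # impulse positions recover the canonical times to < 1 sample
        clip_n = small_delta_corpus.clip_samples
        for i, k in enumerate(impulses):
            t_ms = (k - i * clip_n) / rate * 1000.0
            assert abs(t_ms - small_delta_corpus.canonical_times[i, 0]) \
                < 1000.0 / rate

    def test_left_channel_is_concatenation_of_clips(
        self, small_delta_corpus, tmp_path
    ):
        path = tmp_path / "test.wav"
        s.write_test_file(small_delta_corpus, path)
        left, _, _ = s.read_test_file(path)
        n_clips = len(small_delta_corpus.songs) + len(
            small_delta_corpus.nonsong
        )
        assert len(left) == n_clips * small_delta_corpus.clip_samples

    def test_training_and_streaming_vectors_agree_bitwise(
        self, small_delta_corpus, small_delta_model, default_config
    ):
        """The recognition vector the streaming detector normalizes must be
        bit-identical to the training-set column for the same frame."""
        from sylldet.training import _clip_vectors, window_normalize

        cfg = default_config
        clip = small_delta_corpus.songs[0]
        columns = _clip_vectors(clip, cfg)
        norm_cols = window_normalize(columns)

        streamer = s.FrameStreamer(cfg)
        ring = []
        row = 0
        for i in range(0, len(clip), 50):
            for frame in streamer.feed(clip[i : i + 50]):
                ring.append(frame.power)
                if len(ring) >= cfg.n_frames:
                    xi = np.concatenate(ring[-cfg.n_frames:])
                    np.testing.assert_array_equal(xi, columns[row])
                    np.testing.assert_array_equal(
                        window_normalize(xi), norm_cols[row]
                    )
                    row += 1
        assert row == columns.shape[0]
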