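"""Synthetic corpus generator: determinism, jitter statistics, round-trips."""

from dataclasses import replace

import numpy as np
import pytest

import sylldet as s


def _mini_spec(**kw):
    base = s.CorpusSpec(
        syllables=(
            s.SyllableSpec("harmonic_stack", 40.0, f0=1200.0, n_harmonics=3),
            s.SyllableSpec("broadband_noise", 30.0, band=(2000.0, 6000.0)),
        ),
        n_songs=5,
        n_nonsong=5,
        onset_jitter_sd_ms=0.0,
        amplitude_jitter_sd=0.0,
        noise_snr_db=np.inf,
        seed=3,
        clip_ms=180.0,
    )
    spec = replace(base, **kw)
    if not spec.targets:
        spec = replace(spec, targets=(spec.sequence_start_ms + 35.0,))
    return spec


class TestGenerateCorpus:
    def test_no_randomness_means_identical_songs(self):
        corpus = s.generate_corpus(_mini_spec())
        for clip in corpus.songs[1:]:
            np.testing.assert_array_equal(clip, corpus.songs[0])
        assert np.all(corpus.canonical_times == corpus.canonical_times[0, 0])

    def test_same_seed_reproduces_corpus_exactly(self):
        spec = _mini_spec(onset_jitter_sd_ms=1.5, amplitude_jitter_sd=0.1,
                          noise_snr_db=20.0)
        a, b = s.generate_corpus(spec), s.generate_corpus(spec)
        assert a.corpus_id == b.corpus_id
        for x, y in zip(a.songs + a.nonsong, b.songs + b.nonsong):
            np.testing.assert_array_equal(x, y)
        np.testing.assert_array_equal(a.canonical_times, b.canonical_times)

    def test_realized_onset_jitter_sd_matches_request(self):
        spec = _mini_spec(n_songs=1000, n_nonsong=1, onset_jitter_sd_ms=2.0,
                          clip_ms=200.0)
        corpus = s.generate_corpus(spec)
        sd = np.std(corpus.canonical_times[:, 0], ddof=1)
        assert sd == pytest.approx(2.0, rel=0.10)

    def test_heldout_is_same_song_different_renditions(self):
        spec = _mini_spec(noise_snr_db=25.0, onset_jitter_sd_ms=1.0)
        train = s.generate_corpus(spec)
        held = s.generate_corpus(spec.heldout(seed=99))
        assert held.corpus_id != train.corpus_id
        # same underlying sequence: noiseless renditions would correlate ~1
        a = train.songs[0] - np.mean(train.songs[0])
        b = held.songs[0] - np.mean(held.songs[0])
        lag = np.argmax(np.correlate(a, b, mode="full")) - (len(b) - 1)
        assert abs(lag) < spec.sample_rate * 0.01  # within jitter range
        r = np.corrcoef(np.roll(b, lag), a)[0, 1]
        assert r > 0.9

    def test_all_clips_equal_length(self):
        corpus = s.generate_corpus(_mini_spec(onset_jitter_sd_ms=2.0))
        lengths = {len(c) for c in corpus.songs + corpus.nonsong}
        assert lengths == {corpus.clip_samples}

    def test_nonsong_lacks_song_sequence(self):
        # non-song audio must not correlate with the rendered song
        spec = _mini_spec(n_songs=3, n_nonsong=10)
        corpus = s.generate_corpus(spec)
        song = corpus.songs[0] / np.linalg.norm(corpus.songs[0])
        for clip in corpus.nonsong:
            norm = np.linalg.norm(clip)
            if norm == 0:
                continue
            xc = np.correlate(clip / norm, song, mode="valid")
            assert np.max(np.abs(xc)) < 0.5

    def test_super_nyquist_syllable_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            s.generate_corpus(
                _mini_spec(syllables=(
                    s.SyllableSpec("harmonic_stack", 40.0, f0=9000.0,
                                   n_harmonics=4),
                ))
            )

    def test_target_outside_clip_rejected(self):
        with pytest.raises(ValueError, match="target"):
            s.generate_corpus(_mini_spec(targets=(500.0,)))


class TestDeltaCorpus:
    def test_canonical_time_is_offset_after_impulse(self):
        corpus = s.generate_delta_corpus(n_songs=1, seed=0)
        clip = corpus.songs[0]
        k = int(np.argmax(np.abs(clip)))
        assert corpus.canonical_times[0, 0] == pytest.approx(
            k / corpus.sample_rate * 1000.0 + 5.0, abs=1e-9
        )

    def test_impulse_is_clip_maximum(self):
        corpus = s.generate_delta_corpus(n_songs=5, seed=1)
        for clip in corpus.songs:
            assert np.max(np.abs(clip)) == pytest.approx(1.0)

    def test_phase_sweep_covers_one_hop_uniformly(self):
        hop = 66
        corpus = s.generate_delta_corpus(n_songs=200, seed=2,
                                         phase_span_samples=hop)
        impulses = np.array([int(np.argmax(np.abs(c))) for c in corpus.songs])
        phases = (impulses - impulses[0]) % hop
        # all hop offsets realized, each roughly n_songs/hop times
        counts = np.bincount(phases, minlength=hop)
        assert np.all(counts >= 1)
        assert counts.max() - counts.min() <= 1

    def test_deterministic_given_seed(self):
        a = s.generate_delta_corpus(n_songs=4, seed=7)
        b = s.generate_delta_corpus(n_songs=4, seed=7)
        for x, y in zip(a.songs + a.nonsong, b.songs + b.nonsong):
            np.testing.assert_array_equal(x, y)


class TestCorpusIO:
    def test_round_trip_preserves_samples_and_times(self, tmp_path):
        spec = _mini_spec(onset_jitter_sd_ms=1.0, noise_snr_db=30.0)
        corpus = s.generate_corpus(spec)
        manifest = s.write_corpus(corpus, tmp_path / "corpus")
        assert len(manifest["files"]) == spec.n_songs + spec.n_nonsong
        back = s.read_corpus(tmp_path / "corpus")
        assert back.corpus_id == corpus.corpus_id
        assert back.sample_rate == corpus.sample_rate
        for x, y in zip(corpus.songs + corpus.nonsong,
                        back.songs + back.nonsong):
            np.testing.assert_array_equal(x, y)
        # annotation serialization at nanosecond resolution
        assert np.max(np.abs(back.canonical_times - corpus.canonical_times)) \
            < 1e-6

    def test_missing_annotation_file_errors_with_path(self, tmp_path):
        with pytest.raises(OSError, match=str(tmp_path)):
            s.read_corpus(tmp_path)
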