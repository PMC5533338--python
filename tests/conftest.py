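from dataclasses import replace

import pytest

import sylldet as s


@pytest.fixture(scope="session")
def default_config() -> s.FrameConfig:
    """256-pt FFT, 1.5 ms requested interval, 1-8 kHz, 50 ms window, 44.1 kHz."""
    return s.resolve_frame_config()


@pytest.fixture(scope="session")
def small_delta_corpus() -> s.AnnotatedCorpus:
    """60 δ-syllable songs with the impulse phase swept over one hop."""
    return s.generate_delta_corpus(n_songs=60, seed=11)


@pytest.fixture(scope="session")
def small_delta_model(small_delta_corpus) -> s.DetectorModel:
    """A detector trained with defaults on the small δ corpus.

    Small but fully representative: used by streaming/evaluation tests that
    need a real trained model without paying for a full-size corpus.
    """
    model, _ = s.train_detector(
        small_delta_corpus, train_config=s.TrainConfig(seed=11)
    )
    return model


@pytest.fixture(scope="session")
def tiny_song_corpus() -> s.AnnotatedCorpus:
    """A short stereotyped two-syllable song, 40 songs / 40 non-song."""
    spec = s.CorpusSpec(
        syllables=(
            s.SyllableSpec("harmonic_stack", 50.0, f0=900.0, n_harmonics=5),
            s.SyllableSpec("silence_gap", 20.0),
            s.SyllableSpec("sweep", 50.0, f0=4000.0, f0_end=2500.0,
                           n_harmonics=2),
        ),
        n_songs=40,
        n_nonsong=40,
        onset_jitter_sd_ms=1.0,
        noise_snr_db=30.0,
        seed=5,
        clip_ms=260.0,
    )
    spec = replace(spec, targets=(spec.sequence_start_ms + 90.0,))
    return s.generate_corpus(spec)
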