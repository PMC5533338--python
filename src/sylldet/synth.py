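"""Synthetic aligned song corpora with known ground-truth target times.

Real detector training uses a corpus of time-aligned recordings of one
bird's song plus non-song audio (cage noise, calls, silence).  This module
generates a stand-in: stereotyped "songs" assembled from syllable archetypes
observed in zebra finch song — harmonic stacks, band-limited noise bursts,
and frequency sweeps — rendered into equal-length clips with controllable
onset jitter, amplitude variation, and additive noise, together with
non-song clips that never contain the song sequence.  Because the generator
knows exactly where each song landed, every clip carries exact canonical
target times, which real corpora only have up to alignment error.

It also produces the δ-syllable test signal: a single full-scale impulse per
clip with the target a fixed interval after it, used to measure the timing
resolution inherent in the detection pipeline itself, independent of any
acoustic variability.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .audio import read_wav, write_wav

__all__ = [
    "SyllableSpec",
    "CorpusSpec",
    "AnnotatedCorpus",
    "generate_corpus",
    "generate_delta_corpus",
    "default_song_spec",
    "write_corpus",
    "read_corpus",
]

_EDGE_RAMP_MS = 5.0  # raised-cosine on/offset ramp applied to every syllable
_NOISE_FLOOR = 1e-3  # -60 dBFS background in otherwise silent material


@dataclass(frozen=True)
class SyllableSpec:
    """One syllable archetype.

    kind:
        ``harmonic_stack`` — fundamental ``f0`` with ``n_harmonics``
        overtones at 1/h amplitude (stacked horizontal bands).
        ``sweep`` — linear glide from ``f0`` to ``f0_end`` (with harmonics).
        ``broadband_noise`` — white noise band-passed to ``band``.
        ``silence_gap`` — quiet inter-syllable gap.
    duration_ms:
        Syllable length.
    amplitude:
        Peak linear gain of the rendered syllable.
    """

    kind: str
    duration_ms: float
    f0: float | None = None
    n_harmonics: int = 1
    f0_end: float | None = None
    band: tuple[float, float] | None = None
    amplitude: float = 1.0

    def validate(self, sample_rate: float) -> None:
        nyq = sample_rate / 2.0
        if self.kind not in {"harmonic_stack", "broadband_noise", "sweep", "silence_gap"}:
            raise ValueError(f"unknown syllable kind {self.kind!r}")
        if self.duration_ms <= 0:
            raise ValueError("syllable duration must be positive")
        if self.amplitude <= 0:
            raise ValueError("syllable amplitude must be positive")
        if self.kind in {"harmonic_stack", "sweep"}:
            if self.f0 is None or not (0 < self.f0 < nyq):
                raise ValueError(
                    f"{self.kind} f0={self.f0} Hz must lie in (0, {nyq} Hz)"
                )
            if self.n_harmonics < 1:
                raise ValueError("n_harmonics must be >= 1")
            top = self.f0 * self.n_harmonics
            if self.kind == "sweep":
                if self.f0_end is None or not (0 < self.f0_end < nyq):
                    raise ValueError(
                        f"sweep f0_end={self.f0_end} Hz must lie in (0, {nyq} Hz)"
                    )
                top = max(top, self.f0_end * self.n_harmonics)
            if top >= nyq:
                raise ValueError(
                    f"{self.kind} harmonic {self.n_harmonics} reaches {top} Hz, "
                    f"at or above Nyquist ({nyq} Hz)"
                )
        if self.kind == "broadband_noise":
            if self.band is None or not (0 < self.band[0] < self.band[1] < nyq):
                raise ValueError(
                    f"noise band {self.band} must lie strictly inside (0, {nyq} Hz)"
                )


@dataclass(frozen=True)
class CorpusSpec:
    """Recipe for an aligned synthetic corpus.

    ``targets`` are the canonical trigger times t* in ms, relative to the
    start of the clip in the *nominal* (zero-jitter) rendering; per-song
    onset jitter shifts both the audio and the canonical times together.
    """

    syllables: tuple[SyllableSpec, ...]
    n_songs: int = 1000
    n_nonsong: int = 1000
    onset_jitter_sd_ms: float = 2.0
    amplitude_jitter_sd: float = 0.1
    noise_snr_db: float = 25.0
    sample_rate: float = 44100.0
    seed: int = 0
    targets: tuple[float, ...] = ()
    clip_ms: float | None = None  # None: sequence duration + 160 ms margin
    sequence_seed: int | None = None  # bird identity; None: derived from seed

    @property
    def resolved_sequence_seed(self) -> int:
        """Seed fixing the rendered song itself (the "bird").

        Distinct from ``seed``, which drives per-rendition variation; two
        specs sharing ``resolved_sequence_seed`` describe the same song
        sung on different occasions.
        """
        if self.sequence_seed is not None:
            return self.sequence_seed
        return self.seed

    def heldout(self, seed: int) -> "CorpusSpec":
        """Same song (same bird), fresh renditions: a disjoint test corpus."""
        return replace(
            self, seed=seed, sequence_seed=self.resolved_sequence_seed
        )

    @property
    def sequence_ms(self) -> float:
        return sum(s.duration_ms for s in self.syllables)

    @property
    def resolved_clip_ms(self) -> float:
        return self.clip_ms if self.clip_ms is not None else self.sequence_ms + 160.0

    @property
    def sequence_start_ms(self) -> float:
        """Nominal onset of the syllable sequence within the clip (centered)."""
        return (self.resolved_clip_ms - self.sequence_ms) / 2.0

    def validate(self) -> None:
        if self.n_songs < 1:
            raise ValueError("n_songs must be >= 1")
        if self.onset_jitter_sd_ms < 0:
            raise ValueError("onset_jitter_sd_ms must be >= 0")
        if not self.syllables:
            raise ValueError("corpus needs at least one syllable")
        for s in self.syllables:
            s.validate(self.sample_rate)
        if self.resolved_clip_ms < self.sequence_ms:
            raise ValueError("clip_ms shorter than the syllable sequence")
        for t in self.targets:
            if not (0 <= t <= self.resolved_clip_ms):
                raise ValueError(
                    f"target {t} ms outside clip of {self.resolved_clip_ms} ms"
                )


@dataclass
class AnnotatedCorpus:
    """Equal-length clips plus exact per-song canonical target times (ms)."""

    songs: list[np.ndarray]
    nonsong: list[np.ndarray]
    canonical_times: np.ndarray  # (n_songs, n_targets), ms from clip start
    sample_rate: float
    corpus_id: str
    spec: CorpusSpec | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_targets(self) -> int:
        return self.canonical_times.shape[1]

    @property
    def clip_samples(self) -> int:
        return len(self.songs[0])


def _ramp(n_samples: int, ramp_samples: int) -> np.ndarray:
    env = np.ones(n_samples)
    r = min(ramp_samples, n_samples // 2)
    if r > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = ramp
        env[-r:] = ramp[::-1]
    return env


def _render_syllable(
    syl: SyllableSpec, sample_rate: float, rng: np.random.Generator
) -> np.ndarray:
    n = int(round(syl.duration_ms / 1000.0 * sample_rate))
    t = np.arange(n) / sample_rate
    if syl.kind == "silence_gap":
        return np.zeros(n)
    if syl.kind == "harmonic_stack":
        x = np.zeros(n)
        for h in range(1, syl.n_harmonics + 1):
            x += np.sin(2 * np.pi * h * syl.f0 * t) / h
    elif syl.kind == "sweep":
        # linear glide; harmonics share the fundamental's phase track
        dur = n / sample_rate
        phase = 2 * np.pi * (syl.f0 * t + (syl.f0_end - syl.f0) / (2 * dur) * t**2)
        x = np.zeros(n)
        for h in range(1, syl.n_harmonics + 1):
            x += np.sin(h * phase) / h
    else:  # broadband_noise — a fresh draw per rendition, like a real bird
        white = rng.standard_normal(n)
        sos = sps.butter(
            4, list(syl.band), btype="bandpass", fs=sample_rate, output="sos"
        )
        x = sps.sosfilt(sos, white)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    ramp_samples = int(round(_EDGE_RAMP_MS / 1000.0 * sample_rate))
    return syl.amplitude * x * _ramp(n, ramp_samples)


def _render_sequence(spec: CorpusSpec, rng: np.random.Generator) -> np.ndarray:
    return np.concatenate(
        [_render_syllable(s, spec.sample_rate, rng) for s in spec.syllables]
    )


def _corpus_id(tag: str, payload: dict) -> str:
    blob = json.dumps({"tag": tag, **payload}, sort_keys=True, default=str)
    return hashlib.sha1(blob.encode()).hexdigest()[:16]


def generate_corpus(spec: CorpusSpec) -> AnnotatedCorpus:
    """Render an aligned corpus; deterministic for a given ``(spec, seed)``.

    The song sequence is rendered once per corpus — a stereotyped song is
    the same acoustic object on every rendition, including the fine
    structure of its noise-like syllables.  Each song clip is that sequence
    centered in a fixed-length clip, shifted by a per-song onset jitter
    drawn from N(0, onset_jitter_sd), scaled by a per-song amplitude
    factor, with white noise added at ``noise_snr_db`` relative to the
    rendered song's RMS.  Canonical times are the spec targets shifted by
    the realized (sample-quantized) jitter.  Non-song clips contain
    silence, band-limited noise bursts, and short tonal calls — freshly
    drawn per clip — but never the song sequence.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate
    clip_n = int(round(spec.resolved_clip_ms / 1000.0 * sr))
    nominal_start = int(round(spec.sequence_start_ms / 1000.0 * sr))

    # The song itself is stereotyped: one rendered sequence per corpus
    # (noise-syllable fine structure included), fixed by the corpus seed.
    # Renditions differ only in onset, amplitude, and additive noise.
    seq_rng = np.random.default_rng(
        np.random.SeedSequence([spec.resolved_sequence_seed, 0x5E9])
    )
    base_seq = _render_sequence(spec, seq_rng)

    songs: list[np.ndarray] = []
    canonical = np.empty((spec.n_songs, len(spec.targets)))
    for i in range(spec.n_songs):
        jitter_ms = (
            rng.normal(0.0, spec.onset_jitter_sd_ms)
            if spec.onset_jitter_sd_ms > 0
            else 0.0
        )
        shift = int(round(jitter_ms / 1000.0 * sr))
        amp = 1.0 + (
            rng.normal(0.0, spec.amplitude_jitter_sd)
            if spec.amplitude_jitter_sd > 0
            else 0.0
        )
        amp = max(amp, 0.05)
        seq = amp * base_seq
        start = nominal_start + shift
        if start < 0 or start + len(seq) > clip_n:
            raise ValueError(
                f"song {i}: onset jitter {jitter_ms:.2f} ms pushes the "
                "sequence outside the clip; increase clip_ms"
            )
        clip = np.zeros(clip_n)
        clip[start : start + len(seq)] = seq
        if np.isfinite(spec.noise_snr_db):
            rms = np.sqrt(np.mean(seq**2))
            clip += rng.normal(0.0, rms * 10 ** (-spec.noise_snr_db / 20.0), clip_n)
        songs.append(clip)
        canonical[i] = np.asarray(spec.targets) + shift / sr * 1000.0

    nonsong = [
        _render_nonsong(spec, clip_n, rng) for _ in range(spec.n_nonsong)
    ]

    cid = _corpus_id(
        "song-corpus",
        {"seed": spec.seed, "sequence_seed": spec.resolved_sequence_seed,
         "n_songs": spec.n_songs, "n_nonsong": spec.n_nonsong,
         "syllables": [vars(s) for s in spec.syllables],
         "targets": list(spec.targets), "sr": sr,
         "jitter": spec.onset_jitter_sd_ms, "snr": spec.noise_snr_db,
         "amp": spec.amplitude_jitter_sd, "clip_ms": spec.resolved_clip_ms},
    )
    return AnnotatedCorpus(
        songs=songs, nonsong=nonsong, canonical_times=canonical,
        sample_rate=sr, corpus_id=cid, spec=spec,
    )


def _render_nonsong(
    spec: CorpusSpec, clip_n: int, rng: np.random.Generator
) -> np.ndarray:
    """Negative material: silence floor plus random noise bursts and calls.

    Never contains the song's syllable sequence.
    """
    sr = spec.sample_rate
    clip = rng.normal(0.0, _NOISE_FLOOR, clip_n)
    for _ in range(rng.integers(0, 4)):
        kind = rng.choice(["burst", "call", "hiss"])
        dur = float(rng.uniform(0.03, 0.09))
        n = int(round(dur * sr))
        pos = int(rng.integers(0, max(clip_n - n, 1)))
        amp = float(rng.uniform(0.1, 0.8))
        if kind == "burst":  # cage-noise-like band-limited burst
            lo = float(rng.uniform(300.0, 2000.0))
            hi = float(rng.uniform(lo + 500.0, min(lo + 6000.0, sr / 2 - 100.0)))
            syl = SyllableSpec("broadband_noise", dur * 1000, band=(lo, hi),
                               amplitude=amp)
        elif kind == "call":  # isolated tonal call
            f0 = float(rng.uniform(500.0, 3500.0))
            nh = int(rng.integers(1, 4))
            while f0 * nh >= sr / 2:
                nh -= 1
            syl = SyllableSpec("harmonic_stack", dur * 1000, f0=f0,
                               n_harmonics=max(nh, 1), amplitude=amp)
        else:  # broadband hiss (wing flapping stand-in)
            syl = SyllableSpec("broadband_noise", dur * 1000,
                               band=(100.0, sr / 2 - 200.0), amplitude=amp * 0.5)
        clip[pos : pos + n] += _render_syllable(syl, sr, rng)
    return clip


def generate_delta_corpus(
    n_songs: int = 200,
    target_offset_ms: float = 5.0,
    sample_rate: float = 44100.0,
    seed: int = 0,
    n_nonsong: int | None = None,
    clip_ms: float = 120.0,
    impulse_ms: float = 55.0,
    phase_span_samples: int = 66,
    noise_floor_db: float | None = None,
) -> AnnotatedCorpus:
    """δ-syllable test corpus: one unit impulse per clip, target 5 ms later.

    The impulse position is swept over ``phase_span_samples`` consecutive
    samples across the corpus (song i is offset by ``i*span//n_songs``), so
    that the impulse phase relative to the spectrogram frame grid covers a
    full frame interval — this is what exposes frame-quantization aliasing
    in the timing measurements.  The δ-syllable isolates the timing of the
    pipeline itself, so by default the clips are digitally silent apart
    from the full-scale impulse, making the whole measurement
    deterministic; pass ``noise_floor_db`` (e.g. -60) to add a faint
    Gaussian floor.  Non-song clips are silence (or floor noise) only.
    """
    if n_songs < 1:
        raise ValueError("n_songs must be >= 1")
    if target_offset_ms <= 0:
        raise ValueError("target_offset_ms must be positive")
    if n_nonsong is None:
        n_nonsong = n_songs
    rng = np.random.default_rng(seed)
    sr = sample_rate
    clip_n = int(round(clip_ms / 1000.0 * sr))
    base = int(round(impulse_ms / 1000.0 * sr))
    if base + int((target_offset_ms + 20.0) / 1000.0 * sr) >= clip_n:
        raise ValueError("clip too short for impulse + target + scoring window")

    floor = (
        0.0 if noise_floor_db is None else 10.0 ** (noise_floor_db / 20.0)
    )

    def background() -> np.ndarray:
        if floor == 0.0:
            return np.zeros(clip_n)
        return rng.normal(0.0, floor, clip_n)

    songs = []
    canonical = np.empty((n_songs, 1))
    for i in range(n_songs):
        clip = background()
        k = base + (i * phase_span_samples) // n_songs
        clip[k] = 1.0
        songs.append(clip)
        canonical[i, 0] = k / sr * 1000.0 + target_offset_ms
    nonsong = [background() for _ in range(n_nonsong)]

    cid = _corpus_id(
        "delta-corpus",
        {"seed": seed, "n_songs": n_songs, "n_nonsong": n_nonsong, "sr": sr,
         "offset": target_offset_ms, "clip_ms": clip_ms,
         "impulse_ms": impulse_ms, "span": phase_span_samples,
         "floor_db": noise_floor_db},
    )
    return AnnotatedCorpus(
        songs=songs, nonsong=nonsong, canonical_times=canonical,
        sample_rate=sr, corpus_id=cid, spec=None,
        meta={"kind": "delta", "target_offset_ms": target_offset_ms},
    )


def default_song_spec(
    n_songs: int = 1000,
    n_nonsong: int = 1000,
    seed: int = 0,
    onset_jitter_sd_ms: float = 2.0,
    noise_snr_db: float = 25.0,
    amplitude_jitter_sd: float = 0.1,
    sample_rate: float = 44100.0,
) -> CorpusSpec:
    """A canonical three-syllable test song with one mid-song target.

    Harmonic stack, broadband noise burst, and downward harmonic sweep with
    inter-syllable gaps — the three syllable classes a detector must handle.
    The single target sits at the noise-burst offset, 150 ms into the
    sequence, so the recognition window spans two syllable types.
    """
    syllables = (
        SyllableSpec("harmonic_stack", 70.0, f0=650.0, n_harmonics=8),
        SyllableSpec("silence_gap", 25.0),
        SyllableSpec("broadband_noise", 55.0, band=(1500.0, 7500.0)),
        SyllableSpec("silence_gap", 25.0),
        SyllableSpec("sweep", 70.0, f0=3800.0, f0_end=2200.0, n_harmonics=2),
    )
    spec = CorpusSpec(
        syllables=syllables, n_songs=n_songs, n_nonsong=n_nonsong,
        onset_jitter_sd_ms=onset_jitter_sd_ms, noise_snr_db=noise_snr_db,
        amplitude_jitter_sd=amplitude_jitter_sd, sample_rate=sample_rate,
        seed=seed,
    )
    target = spec.sequence_start_ms + 150.0
    return replace(spec, targets=(target,))


# ---------------------------------------------------------------------------
# on-disk format: one mono WAV per clip + a TSV annotation sidecar
# ---------------------------------------------------------------------------

_ANNOT_NAME = "annotations.tsv"


def write_corpus(corpus: AnnotatedCorpus, directory: str | os.PathLike) -> dict:
    """Write one WAV per clip plus ``annotations.tsv``.

    Clips are stored as IEEE float64 WAV so the corpus round-trips exactly
    through :func:`read_corpus`.  The sidecar has one row per clip:
    ``filename<TAB>is_song<TAB>times``, where ``times`` is a comma-separated
    list of canonical times in ms at nanosecond resolution (empty for
    non-song clips).
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    files = []
    rows = []
    for i, clip in enumerate(corpus.songs):
        name = f"song_{i:05d}.wav"
        write_wav(os.path.join(directory, name), clip, int(corpus.sample_rate),
                  dtype="float64")
        times = ",".join(f"{t:.9f}" for t in corpus.canonical_times[i])
        rows.append(f"{name}\t1\t{times}")
        files.append(name)
    for i, clip in enumerate(corpus.nonsong):
        name = f"nonsong_{i:05d}.wav"
        write_wav(os.path.join(directory, name), clip, int(corpus.sample_rate),
                  dtype="float64")
        rows.append(f"{name}\t0\t")
        files.append(name)
    annot = os.path.join(directory, _ANNOT_NAME)
    header = (
        f"# sylldet corpus\tid={corpus.corpus_id}\t"
        f"sample_rate={corpus.sample_rate:.6f}\n"
        "# filename\tis_song\tcanonical_times_ms\n"
    )
    with open(annot, "w") as fh:
        fh.write(header)
        fh.write("\n".join(rows) + "\n")
    return {"directory": directory, "annotations": annot, "files": files,
            "n_songs": len(corpus.songs), "n_nonsong": len(corpus.nonsong)}


def read_corpus(directory: str | os.PathLike) -> AnnotatedCorpus:
    """Read a corpus written by :func:`write_corpus`."""
    directory = os.fspath(directory)
    annot = os.path.join(directory, _ANNOT_NAME)
    if not os.path.exists(annot):
        raise OSError(f"no {_ANNOT_NAME} found in {directory!r}")
    with open(annot) as fh:
        lines = fh.read().splitlines()
    if not lines or "sylldet corpus" not in lines[0]:
        raise OSError(f"{annot!r} is not a sylldet corpus annotation file")
    fields = dict(
        kv.split("=", 1) for kv in lines[0].split("\t")[1:] if "=" in kv
    )
    corpus_id = fields.get("id", "unknown")
    sample_rate = float(fields.get("sample_rate", "0"))
    songs, nonsong, times = [], [], []
    for line in lines[1:]:
        if not line or line.startswith("#"):
            continue
        name, is_song, t_str = line.split("\t")
        clip, rate = read_wav(os.path.join(directory, name))
        if rate != int(round(sample_rate)):
            raise SampleRateError(name, rate, sample_rate)
        if is_song == "1":
            songs.append(clip)
            times.append([float(t) for t in t_str.split(",")] if t_str else [])
        else:
            nonsong.append(clip)
    canonical = np.asarray(times, dtype=np.float64)
    if canonical.ndim == 1:  # zero targets
        canonical = canonical.reshape(len(songs), 0)
    return AnnotatedCorpus(
        songs=songs, nonsong=nonsong, canonical_times=canonical,
        sample_rate=sample_rate, corpus_id=corpus_id, spec=None,
    )


class SampleRateError(OSError):
    def __init__(self, name, rate, expected):
        super().__init__(
            f"clip {name!r} has sample rate {rate}, corpus declares {expected}"
        )
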