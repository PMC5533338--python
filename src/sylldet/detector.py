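"""Simulated-streaming detection: chunked audio in, de-bounced events out.

This is a faithful software rendition of the realtime loop: audio arrives
in small chunks (8–32 samples emulates typical hardware buffer sizes) and
is appended to a circular audio buffer; every ``hop`` new samples a
Hamming-windowed power spectrum is appended to the FFT ring; once the ring
holds a full recognition window the vector is normalized exactly as during
training and pushed through the network; a syllable triggers on an upward
threshold crossing (previous frame at or below θ, current above), after
which that syllable is suppressed for the de-bounce interval (default
100 ms, in whole frames rounded up).  The emitted event sequence is
invariant to how the audio is chunked.

Also writes the stereo ground-truth test file: all clips concatenated on
the left channel, a unit impulse at every canonical target time on the
right, so any playback-plus-scope rig (or the offline evaluator) can score
the detector against ground truth.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np

from .audio import SampleRateMismatch, read_wav, write_wav
from .model import DetectorModel
from .synth import AnnotatedCorpus

__all__ = [
    "DetectionEvent",
    "StreamDetector",
    "detect_file",
    "write_test_file",
    "read_test_file",
    "write_event_log",
]


@dataclass(frozen=True)
class DetectionEvent:
    """One trigger: which syllable fired, when, and at what output value.

    ``trigger_sample`` is the number of samples consumed when the triggering
    frame became available (the end of its analysis window) — the earliest
    causally meaningful instant for the detection.
    """

    syllable: int
    trigger_sample: int
    trigger_time_s: float
    output_value: float


class StreamDetector:
    """Stateful detector over a chunked audio stream.

    The state is the circular audio buffer (inside the frame streamer), the
    FFT ring of the ``n_frames`` most recent spectra, the previous network
    outputs (for edge triggering), and the last trigger frame per syllable
    (for de-bouncing).  Evaluation continues during the de-bounce window;
    only event emission is suppressed.
    """

    def __init__(self, model: DetectorModel, sample_rate: float | None = None):
        from .frontend import FrameStreamer

        if sample_rate is not None and sample_rate != model.sample_rate:
            raise SampleRateMismatch(
                f"stream at {sample_rate} Hz, but the model was trained at "
                f"{model.sample_rate} Hz"
            )
        self.model = model
        cfg = model.config
        self._streamer = FrameStreamer(cfg)
        self._ring = np.zeros((cfg.n_frames, cfg.n_bins))
        self._filled = 0
        self._prev_out = np.full(model.n_targets, -np.inf)
        self._last_trigger_frame = np.full(model.n_targets, -np.inf)
        self._debounce_frames = math.ceil(
            model.debounce_ms / cfg.effective_interval_ms
        )

    def feed(self, chunk: np.ndarray) -> list[DetectionEvent]:
        """Consume a chunk of samples; return any events it completes."""
        events: list[DetectionEvent] = []
        cfg = self.model.config
        for frame in self._streamer.feed(chunk):
            self._ring = np.roll(self._ring, -1, axis=0)
            self._ring[-1] = frame.power
            self._filled = min(self._filled + 1, cfg.n_frames)
            if self._filled < cfg.n_frames:
                continue
            xi = self._ring.ravel()  # oldest -> newest frame blocks
            out = self.model.evaluate_window(xi)
            crossing = (out > self.model.thresholds) & (
                self._prev_out <= self.model.thresholds
            )
            quiet = (
                frame.frame_index - self._last_trigger_frame
                >= self._debounce_frames
            )
            for k in np.flatnonzero(crossing & quiet):
                events.append(
                    DetectionEvent(
                        syllable=int(k),
                        trigger_sample=frame.end_sample,
                        trigger_time_s=frame.end_sample / cfg.sample_rate,
                        output_value=float(out[k]),
                    )
                )
                self._last_trigger_frame[k] = frame.frame_index
            self._prev_out = out
        return events


def detect_file(
    model: DetectorModel,
    wav_path: str | os.PathLike,
    chunk_samples: int = 32,
) -> list[DetectionEvent]:
    """Run the streaming detector over a mono WAV file in small chunks."""
    audio, rate = read_wav(wav_path)
    if audio.ndim != 1:
        raise ValueError(f"{wav_path!r} is not mono")
    det = StreamDetector(model, sample_rate=rate)
    events: list[DetectionEvent] = []
    for start in range(0, len(audio), chunk_samples):
        events.extend(det.feed(audio[start : start + chunk_samples]))
    return events


def write_test_file(
    corpus: AnnotatedCorpus, path: str | os.PathLike
) -> np.ndarray:
    """Write the stereo ground-truth test file.

    Left channel: every clip concatenated, songs first then non-song (order
    recorded in a sidecar manifest next to the file).  Right channel: a
    unit impulse at each canonical target time, silent elsewhere.  Returns
    the impulse sample positions.
    """
    sr = corpus.sample_rate
    left = np.concatenate(corpus.songs + corpus.nonsong)
    right = np.zeros_like(left)
    impulse_samples = []
    offset = 0
    for i, clip in enumerate(corpus.songs):
        for t_ms in corpus.canonical_times[i]:
            k = offset + int(round(t_ms / 1000.0 * sr))
            right[k] = 1.0
            impulse_samples.append(k)
        offset += len(clip)
    write_wav(path, np.column_stack([left, right]), int(sr), dtype="float32")
    manifest = os.fspath(path) + ".manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write(f"# sylldet test file\tid={corpus.corpus_id}\t"
                 f"sample_rate={sr:.6f}\n# position\tkind\tindex\tlength\n")
        pos = 0
        for kind, clips in (("song", corpus.songs), ("nonsong", corpus.nonsong)):
            for i, clip in enumerate(clips):
                fh.write(f"{pos}\t{kind}\t{i}\t{len(clip)}\n")
                pos += len(clip)
    return np.asarray(impulse_samples)


def read_test_file(
    path: str | os.PathLike,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Read a stereo test file: ``(audio, ground_truth_samples, rate)``.

    Ground-truth times are the sample indices where the right channel is
    nonzero (above half scale).
    """
    data, rate = read_wav(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path!r} is not a stereo ground-truth test file")
    left, right = data[:, 0], data[:, 1]
    return left, np.flatnonzero(right > 0.5), rate


def write_event_log(
    events: list[DetectionEvent], path: str | os.PathLike
) -> None:
    """Delimited text log: syllable, trigger_sample, trigger_time_s, output."""
    with open(os.fspath(path), "w") as fh:
        fh.write("syllable\ttrigger_sample\ttrigger_time_s\toutput_value\n")
        for e in events:
            fh.write(
                f"{e.syllable}\t{e.trigger_sample}\t"
                f"{e.trigger_time_s:.9f}\t{e.output_value:.9g}\n"
            )
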