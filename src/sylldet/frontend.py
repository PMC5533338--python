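"""Spectral front end: rolling band-limited power spectra on a quantized hop.

The detector consumes a spectrogram computed at a nominally fixed frame
interval (e.g. 1.5 ms).  Because the interval must correspond to an integer
number of audio samples, the requested interval is quantized: at 44.1 kHz a
1.5 ms request becomes a 66-sample hop and a true interval of
66/44.1 ≈ 1.4966 ms.  All timing downstream (target placement, latency,
de-bouncing) is expressed in units of this *effective* interval.

Frames are causal: a frame exists only once its newest audio sample has
arrived, and its timestamp is the end of its analysis window.  The first
frame is emitted once ``fft_size`` samples have accumulated; frame ``k`` ends
at sample ``fft_size + k * hop``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "FrameConfig",
    "SpectralFrame",
    "FrameStreamer",
    "resolve_frame_config",
    "band_bins",
    "compute_frame",
    "frame_powers",
    "stream_frames",
]


def _round_half_away(x: float) -> int:
    """Nearest integer, ties rounded half away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class FrameConfig:
    """Geometry of the spectral front end and the recognition window.

    Attributes
    ----------
    fft_size : int
        Length of the analysis window in samples (also the FFT length).
    sample_rate : float
        Audio sample rate in Hz.
    hop : int
        New audio samples consumed per frame (the quantized frame interval).
    requested_interval_ms : float
        The frame interval that was asked for.
    effective_interval_ms : float
        ``hop / sample_rate`` in ms — the true frame interval actually used.
    band : (float, float)
        Frequency band (Hz, inclusive on both edges) whose FFT bins feed the
        classifier.
    window_ms : float
        Nominal duration of the recognition window.
    n_frames : int
        Number of consecutive frames in the recognition window,
        ``round(window_ms / effective_interval_ms)``.
    """

    fft_size: int
    sample_rate: float
    hop: int
    requested_interval_ms: float
    effective_interval_ms: float
    band: tuple[float, float]
    window_ms: float
    n_frames: int
    bins: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def input_dim(self) -> int:
        """Length of the flattened recognition vector, |F|·|T|."""
        return self.n_bins * self.n_frames

    def frame_end_sample(self, k: int | np.ndarray):
        """Samples consumed when frame ``k`` becomes available."""
        return self.fft_size + k * self.hop

    def frame_time_ms(self, k: int | np.ndarray):
        """Timestamp (ms) of frame ``k`` — the end of its analysis window."""
        return self.frame_end_sample(k) / self.sample_rate * 1000.0

    def frame_containing(self, t_ms: float) -> int:
        """Index of the first frame whose end time is >= ``t_ms``.

        This is the causal frame in which the instant ``t_ms`` falls: the
        earliest frame whose analysis window has already seen that instant.
        """
        k = math.ceil((t_ms / 1000.0 * self.sample_rate - self.fft_size) / self.hop)
        return max(k, 0)

    def to_dict(self) -> dict:
        return {
            "fft_size": self.fft_size,
            "sample_rate": self.sample_rate,
            "requested_interval_ms": self.requested_interval_ms,
            "band": list(self.band),
            "window_ms": self.window_ms,
        }

    @staticmethod
    def from_dict(d: dict) -> "FrameConfig":
        return resolve_frame_config(
            fft_size=int(d["fft_size"]),
            requested_interval_ms=float(d["requested_interval_ms"]),
            sample_rate=float(d["sample_rate"]),
            band=tuple(d["band"]),
            window_ms=float(d["window_ms"]),
        )


@dataclass(frozen=True)
class SpectralFrame:
    """One column of the rolling spectrogram.

    ``end_sample`` is the number of audio samples consumed when this frame
    was computed (the analysis window covers samples
    ``end_sample - fft_size .. end_sample - 1``).
    """

    frame_index: int
    end_sample: int
    power: np.ndarray


def band_bins(
    fft_size: int, sample_rate: float, band: tuple[float, float]
) -> np.ndarray:
    """Indices of one-sided FFT bins whose center lies in ``band`` (inclusive)."""
    f_lo, f_hi = band
    freqs = np.arange(fft_size // 2 + 1) * (sample_rate / fft_size)
    bins = np.flatnonzero((freqs >= f_lo) & (freqs <= f_hi))
    if len(bins) == 0:
        raise ValueError(
            f"band {band} Hz contains no FFT bin centers "
            f"(bin spacing {sample_rate / fft_size:.3f} Hz)"
        )
    return bins


def resolve_frame_config(
    fft_size: int = 256,
    requested_interval_ms: float = 1.5,
    sample_rate: float = 44100.0,
    band: tuple[float, float] = (1000.0, 8000.0),
    window_ms: float = 50.0,
) -> FrameConfig:
    """Quantize the requested frame interval and fix the window geometry.

    The hop is the nearest integer number of samples to
    ``sample_rate * requested_interval_ms``; the effective interval is then
    recomputed from the hop, so e.g. (256, 1.0 ms, 44.1 kHz) resolves to a
    44-sample hop and an effective interval of 44/44.1 ≈ 0.9977 ms.
    """
    if requested_interval_ms <= 0:
        raise ValueError("requested_interval_ms must be positive")
    if not (0.0 <= band[0] <= band[1] <= sample_rate / 2):
        raise ValueError(
            f"band {band} must lie within (0, Nyquist={sample_rate / 2} Hz)"
        )
    hop = _round_half_away(sample_rate * requested_interval_ms / 1000.0)
    if hop < 1:
        raise ValueError(
            f"frame interval {requested_interval_ms} ms is under one sample "
            f"at {sample_rate} Hz"
        )
    if hop > fft_size:
        raise ValueError(
            f"hop {hop} exceeds fft_size {fft_size}: frames would skip audio"
        )
    effective_ms = hop / sample_rate * 1000.0
    n_frames = _round_half_away(window_ms / effective_ms)
    if n_frames < 1:
        raise ValueError("recognition window shorter than one frame")
    return FrameConfig(
        fft_size=fft_size,
        sample_rate=sample_rate,
        hop=hop,
        requested_interval_ms=requested_interval_ms,
        effective_interval_ms=effective_ms,
        band=tuple(band),
        window_ms=window_ms,
        n_frames=n_frames,
        bins=band_bins(fft_size, sample_rate, band),
    )


def _hamming(n: int) -> np.ndarray:
    # symmetric Hamming, as used by the reference spectral pipeline
    return np.hamming(n)


def power_spectrum(window: np.ndarray, fft_size: int) -> np.ndarray:
    """One-sided power spectrum of a Hamming-windowed sample block.

    No 1/N or window-gain normalization is applied: the detector z-scores
    every recognition window, so absolute spectral scale cancels — what
    matters is that training and runtime use the identical computation.
    """
    if window.shape[-1] != fft_size:
        raise ValueError(
            f"expected {fft_size}-sample window, got {window.shape[-1]}"
        )
    spec = np.fft.rfft(window * _hamming(fft_size), axis=-1)
    return np.abs(spec) ** 2


def compute_frame(window: np.ndarray, config: FrameConfig) -> np.ndarray:
    """Band-limited power vector for one ``fft_size``-sample window."""
    return power_spectrum(np.asarray(window, dtype=np.float64), config.fft_size)[
        ..., config.bins
    ]


def frame_powers(audio: np.ndarray, config: FrameConfig) -> np.ndarray:
    """All frames of a clip at once: shape ``(n_frames_total, n_bins)``.

    Frame ``k`` covers samples ``k*hop .. k*hop + fft_size - 1``; bit-identical
    to feeding the same audio through :class:`FrameStreamer`.
    """
    audio = np.asarray(audio, dtype=np.float64)
    if len(audio) < config.fft_size:
        raise ValueError(
            f"clip of {len(audio)} samples is shorter than one "
            f"{config.fft_size}-sample analysis window"
        )
    windows = sliding_window_view(audio, config.fft_size)[:: config.hop]
    return compute_frame(windows, config)


class FrameStreamer:
    """Incremental spectrogram: feed audio in arbitrary chunks, get frames.

    The emitted frame sequence is invariant to how the audio is chunked.
    """

    def __init__(self, config: FrameConfig):
        self.config = config
        self._tail = np.empty(0, dtype=np.float64)  # most recent samples
        self._total = 0  # samples consumed so far
        self._next_frame = 0  # index of the next frame to emit

    def feed(self, chunk: np.ndarray) -> list[SpectralFrame]:
        chunk = np.asarray(chunk, dtype=np.float64).ravel()
        if len(chunk) == 0:
            return []
        cfg = self.config
        buf = np.concatenate([self._tail, chunk])
        buf_start = self._total - len(self._tail)  # absolute index of buf[0]
        self._total += len(chunk)

        frames: list[SpectralFrame] = []
        while True:
            end = cfg.frame_end_sample(self._next_frame)
            if end > self._total:
                break
            window = buf[end - cfg.fft_size - buf_start : end - buf_start]
            frames.append(
                SpectralFrame(self._next_frame, end, compute_frame(window, cfg))
            )
            self._next_frame += 1

        keep = min(len(buf), cfg.fft_size)
        self._tail = buf[len(buf) - keep :].copy()
        return frames


def stream_frames(audio: np.ndarray, config: FrameConfig) -> list[SpectralFrame]:
    """Frame sequence for a whole clip (single-feed convenience wrapper)."""
    return FrameStreamer(config).feed(audio)
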