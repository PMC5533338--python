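"""Training-set assembly: recognition vectors, targets, and normalization.

At each frame time the detector sees the recognition region — the last
``n_frames`` band-limited power spectra — flattened into a vector of length
|F|·|T| (frame blocks oldest→newest, each block the |F| band powers of one
frame).  Two normalizations are applied, and must be byte-identical between
training and the streaming detector:

1. *Window z-score*: each recognition vector is shifted/scaled to mean 0,
   SD 1 over its own elements, removing overall amplitude (bird moving
   around the cage, recording gain).  A constant window (digital silence)
   maps to the zero vector.
2. *Feature z-score*: each element (row of the training matrix) is
   shifted/scaled to mean 0, SD 1 across the whole training set; the
   (mu, sigma) transform is stored with the model and applied to unseen
   audio at runtime.

Targets are Gaussian bumps in time (SD ``target_sd_ms``, default 2 ms)
rather than a strict 0/1 indicator: frames adjacent to the target look
nearly identical to the target frame, and a hard boundary would demand the
network separate the inseparable.  The bump is centered on the frame
*containing* t* — the first frame whose analysis window has seen t* — and
truncated at ±3 SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frontend import FrameConfig, frame_powers
from .synth import AnnotatedCorpus

__all__ = [
    "FeatureNorm",
    "TrainingSet",
    "window_normalize",
    "fit_feature_norm",
    "build_training_set",
]

SIGMA_FLOOR = 1e-8  # features constant across the corpus must not divide by ~0


def window_normalize(xi: np.ndarray, out: np.ndarray | None = None) -> np.ndarray:
    """Z-score each recognition vector over its own elements (sample SD).

    Accepts a single vector ``(d,)`` or a batch ``(n, d)`` of row vectors.
    Constant (zero-variance) windows map to the zero vector.
    """
    xi = np.asarray(xi, dtype=np.float64)
    batch = xi.ndim == 2
    # constancy judged on the raw values: the SD of a constant window can
    # come out as rounding noise rather than exactly zero
    constant = np.ptp(xi, axis=-1, keepdims=True) == 0.0
    mean = xi.mean(axis=-1, keepdims=True)
    sd = xi.std(axis=-1, ddof=1, keepdims=True)
    if out is None:
        out = np.empty_like(xi)
    np.subtract(xi, mean, out=out)
    constant |= (sd == 0.0) | ~np.isfinite(sd)
    safe_sd = np.where(constant, 1.0, sd)
    np.divide(out, safe_sd, out=out)
    if batch:
        out[constant.ravel()] = 0.0
    elif constant:
        out[:] = 0.0
    return out


@dataclass
class FeatureNorm:
    """Per-feature (mu, sigma) saved with the model and applied at runtime."""

    mu: np.ndarray
    sigma: np.ndarray

    def apply(self, xi: np.ndarray, out: np.ndarray | None = None) -> np.ndarray:
        if out is None:
            out = np.empty_like(xi, dtype=np.float64)
        np.subtract(xi, self.mu, out=out)
        np.divide(out, self.sigma, out=out)
        return out


def fit_feature_norm(X: np.ndarray) -> FeatureNorm:
    """Fit per-feature mean/SD over the training set.

    ``X`` has one recognition vector per row, so features are columns;
    sample-SD convention (n-1), SDs floored at ``SIGMA_FLOOR``.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("feature normalization needs at least 2 training vectors")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=1)
    sigma = np.maximum(sigma, SIGMA_FLOOR)
    return FeatureNorm(mu=mu, sigma=sigma)


@dataclass
class TrainingSet:
    """The training matrix and everything needed to interpret its columns.

    ``X`` holds one recognition vector per row (it is the transpose of the
    conventional column-per-sample training matrix, kept row-major so each
    vector is contiguous exactly as the streaming detector builds it).
    ``stage`` tracks which normalizations have been applied in place.
    """

    X: np.ndarray  # (n_columns, |F|*|T|)
    targets: np.ndarray  # (n_columns, n_targets)
    clip_kind: np.ndarray  # (n_columns,) bool: True for song clips
    clip_index: np.ndarray  # (n_columns,) index within songs / nonsong list
    frame_index: np.ndarray  # (n_columns,) frame index within the clip
    time_ms: np.ndarray  # (n_columns,) frame end time within the clip
    config: FrameConfig
    stage: str = "raw"

    @property
    def n_columns(self) -> int:
        return self.X.shape[0]

    @property
    def n_targets(self) -> int:
        return self.targets.shape[1]


def _clip_vectors(audio: np.ndarray, config: FrameConfig) -> np.ndarray:
    """Recognition vectors for every usable frame of one clip.

    Returns ``(n_usable, n_frames * n_bins)``; row r is the window ending at
    frame ``r + n_frames - 1`` (frames before the FFT ring fills are skipped).
    """
    powers = frame_powers(audio, config)  # (n_total, n_bins)
    n_total = powers.shape[0]
    n_usable = n_total - config.n_frames + 1
    if n_usable < 1:
        raise ValueError(
            f"clip has {n_total} frames, fewer than the {config.n_frames}-frame "
            "recognition window"
        )
    out = np.empty((n_usable, config.n_frames * config.n_bins))
    for r in range(n_usable):
        out[r] = powers[r : r + config.n_frames].ravel()
    return out


def _gaussian_targets(
    frame_times_ms: np.ndarray,
    canonical_ms: np.ndarray,
    config: FrameConfig,
    target_sd_ms: float,
    clip_label: str,
) -> np.ndarray:
    """Per-column targets for one song: truncated Gaussian per syllable.

    The bump peaks (exactly 1) at the frame containing t*; zero beyond
    ±3 SD.
    """
    y = np.zeros((len(frame_times_ms), len(canonical_ms)))
    for k, t_star in enumerate(canonical_ms):
        peak_frame = config.frame_containing(t_star)
        peak_ms = config.frame_time_ms(peak_frame)
        if not (frame_times_ms[0] <= peak_ms <= frame_times_ms[-1]):
            raise ValueError(
                f"{clip_label}: target {t_star:.3f} ms maps to frame time "
                f"{peak_ms:.3f} ms, outside the usable range "
                f"[{frame_times_ms[0]:.3f}, {frame_times_ms[-1]:.3f}] ms"
            )
        d = frame_times_ms - peak_ms
        g = np.exp(-(d**2) / (2.0 * target_sd_ms**2))
        g[np.abs(d) > 3.0 * target_sd_ms] = 0.0
        y[:, k] = g
    return y


def build_training_set(
    corpus: AnnotatedCorpus,
    config: FrameConfig,
    target_sd_ms: float = 2.0,
) -> TrainingSet:
    """Assemble the (raw) training matrix and target matrix from a corpus.

    One column per usable frame of every song and non-song clip; non-song
    columns (and song columns outside the Gaussian support) carry target 0
    and act as the negative examples.
    """
    blocks, target_blocks = [], []
    kinds, clip_idx, frame_idx, times = [], [], [], []
    n_targets = corpus.n_targets

    for is_song, clips in ((True, corpus.songs), (False, corpus.nonsong)):
        for i, clip in enumerate(clips):
            vecs = _clip_vectors(clip, config)
            n = vecs.shape[0]
            frames = np.arange(config.n_frames - 1, config.n_frames - 1 + n)
            t_ms = config.frame_time_ms(frames)
            if is_song:
                tgt = _gaussian_targets(
                    t_ms, corpus.canonical_times[i], config, target_sd_ms,
                    clip_label=f"song {i}",
                )
            else:
                tgt = np.zeros((n, n_targets))
            blocks.append(vecs)
            target_blocks.append(tgt)
            kinds.append(np.full(n, is_song))
            clip_idx.append(np.full(n, i))
            frame_idx.append(frames)
            times.append(t_ms)

    return TrainingSet(
        X=np.ascontiguousarray(np.concatenate(blocks)),
        targets=np.concatenate(target_blocks),
        clip_kind=np.concatenate(kinds),
        clip_index=np.concatenate(clip_idx),
        frame_index=np.concatenate(frame_idx),
        time_ms=np.concatenate(times),
        config=config,
        stage="raw",
    )
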