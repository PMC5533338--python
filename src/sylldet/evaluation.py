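"""Quantification: per-frame accuracy, detection latency, and jitter.

Accuracy is scored per frame on raw (un-de-bounced) outputs: the
true-positive rate is the percentage of canonical events with at least one
above-threshold frame within ±Δt, and the false-positive rate the
percentage of frames outside every event window that are above threshold —
a definition that remains meaningful on unsegmented streams of calls and
cage noise.

Timing: latency is the signed offset from the canonical target time to the
trigger (a detector that fires at 203 ms for a 200 ms target has a latency
of 3 ms; negative latencies occur because the network output can cross
threshold while still rising toward its peak).  Jitter is the sample
standard deviation of latency over detected events.  The *ideal* detector
is the offline, zero-buffer path — frames at exact hop positions, trigger
at the end sample of the first above-threshold frame in the event window —
which isolates the timing inherent in the FFT size, the frame interval,
and the Gaussian target smoothing from all I/O and scheduling overhead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from warnings import warn

import numpy as np
import pandas as pd

from .model import DetectorModel
from .synth import AnnotatedCorpus
from .thresholds import ClipOutputs, CostConfig, count_errors
from .training import window_normalize, _clip_vectors

__all__ = [
    "AccuracyReport",
    "TimingReport",
    "corpus_outputs",
    "evaluate_accuracy",
    "measure_timing",
    "ideal_timing",
    "sweep_frame_interval",
]


@dataclass
class AccuracyReport:
    """Per-syllable per-frame classification performance."""

    tp: np.ndarray
    fn: np.ndarray
    fp: np.ndarray
    n_events: np.ndarray
    n_negative_frames: np.ndarray

    @property
    def tp_pct(self) -> np.ndarray:
        """Percent of canonical events detected (NaN if no events)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.n_events > 0, 100.0 * self.tp / self.n_events, np.nan
            )

    @property
    def fp_pct(self) -> np.ndarray:
        """Percent of non-event frames above threshold."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.n_negative_frames > 0,
                100.0 * self.fp / self.n_negative_frames,
                0.0,
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "syllable": np.arange(len(self.tp)),
                "n_events": self.n_events,
                "tp": self.tp,
                "fn": self.fn,
                "fp_frames": self.fp,
                "n_negative_frames": self.n_negative_frames,
                "tp_pct": self.tp_pct,
                "fp_pct": self.fp_pct,
            }
        )


@dataclass
class TimingReport:
    """Signed latencies (ms) of matched detections for one syllable."""

    latencies_ms: np.ndarray = field(repr=False)
    n_events: int = 0

    @property
    def n_detected(self) -> int:
        return len(self.latencies_ms)

    @property
    def latency_mean_ms(self) -> float:
        return float(np.mean(self.latencies_ms)) if self.n_detected else np.nan

    @property
    def jitter_ms(self) -> float:
        """Sample SD of latency over detected events (0 for a single event)."""
        if self.n_detected == 0:
            return np.nan
        if self.n_detected == 1:
            return 0.0
        return float(np.std(self.latencies_ms, ddof=1))


def clip_outputs(model: DetectorModel, audio: np.ndarray) -> ClipOutputs:
    """Offline (un-de-bounced) network outputs for every usable frame."""
    cfg = model.config
    vecs = _clip_vectors(np.asarray(audio, dtype=np.float64), cfg)
    xi = window_normalize(vecs, out=vecs)
    out = model.forward(model.feature_norm.apply(xi, out=xi))
    n = out.shape[0]
    frames = np.arange(cfg.n_frames - 1, cfg.n_frames - 1 + n)
    return ClipOutputs(
        times_ms=cfg.frame_time_ms(frames), outputs=out, is_song=False
    )


def corpus_outputs(
    model: DetectorModel, corpus: AnnotatedCorpus
) -> list[ClipOutputs]:
    """Offline outputs for every clip, with canonical events attached."""
    clips = []
    for i, song in enumerate(corpus.songs):
        c = clip_outputs(model, song)
        c.is_song = True
        c.events = [
            np.atleast_1d(corpus.canonical_times[i, k])
            for k in range(corpus.n_targets)
        ]
        clips.append(c)
    clips.extend(clip_outputs(model, clip) for clip in corpus.nonsong)
    return clips


def evaluate_accuracy(
    model: DetectorModel,
    corpus: AnnotatedCorpus,
    cost: CostConfig | None = None,
) -> AccuracyReport:
    """Per-frame accuracy of the stored thresholds on a corpus.

    The corpus should be disjoint from the training corpus for an unbiased
    estimate; a warning is raised when the corpus IDs coincide.
    """
    if not corpus.songs and not corpus.nonsong:
        raise ValueError("cannot evaluate on an empty corpus")
    if model.train_corpus_id and corpus.corpus_id == model.train_corpus_id:
        warn(
            "evaluating on the training corpus: accuracy will be optimistic",
            stacklevel=2,
        )
    cost = cost or model.cost
    clips = corpus_outputs(model, corpus)
    counts = [
        count_errors(clips, float(model.thresholds[k]), cost, k)
        for k in range(model.n_targets)
    ]
    return AccuracyReport(
        tp=np.array([c.tp for c in counts]),
        fn=np.array([c.fn for c in counts]),
        fp=np.array([c.fp for c in counts]),
        n_events=np.array([c.n_events for c in counts]),
        n_negative_frames=np.array([c.n_negative_frames for c in counts]),
    )


def measure_timing(
    event_times_ms: np.ndarray,
    canonical_times_ms: np.ndarray,
    accept_window_ms: float = 10.0,
) -> TimingReport:
    """Match triggers to canonical events and summarize latency.

    Each canonical event (in time order) is greedily matched one-to-one to
    the nearest unused trigger within ±Δt; latency is trigger − canonical
    (signed, ms).
    """
    triggers = np.sort(np.asarray(event_times_ms, dtype=np.float64))
    used = np.zeros(len(triggers), dtype=bool)
    latencies = []
    canonical = np.sort(np.asarray(canonical_times_ms, dtype=np.float64))
    for t_star in canonical:
        free = np.flatnonzero(~used)
        if len(free) == 0:
            break
        d = triggers[free] - t_star
        j = int(np.argmin(np.abs(d)))
        if abs(d[j]) <= accept_window_ms:
            used[free[j]] = True
            latencies.append(d[j])
    return TimingReport(
        latencies_ms=np.asarray(latencies), n_events=len(canonical)
    )


def ideal_timing(
    model: DetectorModel,
    corpus: AnnotatedCorpus,
    cost: CostConfig | None = None,
) -> list[TimingReport]:
    """Zero-buffer offline timing, one report per target syllable.

    For each song, the trigger is the end sample of the first frame within
    the event window whose output exceeds the stored threshold; undetected
    events contribute no latency.
    """
    cost = cost or model.cost
    half = cost.accept_window_ms
    latencies: list[list[float]] = [[] for _ in range(model.n_targets)]
    n_events = np.zeros(model.n_targets, dtype=int)
    for i, song in enumerate(corpus.songs):
        c = clip_outputs(model, song)
        for k in range(model.n_targets):
            t_star = corpus.canonical_times[i, k]
            n_events[k] += 1
            in_win = np.abs(c.times_ms - t_star) <= half
            above = in_win & (c.outputs[:, k] > model.thresholds[k])
            hits = np.flatnonzero(above)
            if len(hits):
                latencies[k].append(c.times_ms[hits[0]] - t_star)
    return [
        TimingReport(latencies_ms=np.asarray(latencies[k]),
                     n_events=int(n_events[k]))
        for k in range(model.n_targets)
    ]


def sweep_frame_interval(
    train_corpus: AnnotatedCorpus,
    intervals_ms: list[float],
    eval_corpus: AnnotatedCorpus | None = None,
    target_sd_ms: float = 2.0,
    train_config=None,
    cost: CostConfig | None = None,
    fft_size: int = 256,
    band: tuple[float, float] = (1000.0, 8000.0),
    window_ms: float = 50.0,
) -> pd.DataFrame:
    """Latency/jitter/accuracy tradeoff over spectrogram frame intervals.

    Trains one detector per interval on ``train_corpus`` and evaluates on
    ``eval_corpus`` (default: the training corpus).  Shorter frame
    intervals generally reduce both latency and jitter at the price of
    training and runtime cost.
    """
    from .pipeline import train_detector

    eval_corpus = eval_corpus or train_corpus
    rows = []
    for interval in intervals_ms:
        model, _ = train_detector(
            train_corpus,
            frame_interval_ms=interval,
            fft_size=fft_size,
            band=band,
            window_ms=window_ms,
            target_sd_ms=target_sd_ms,
            train_config=train_config,
            cost=cost,
        )
        import warnings

        with warnings.catch_warnings():
            if eval_corpus is train_corpus:
                warnings.simplefilter("ignore")
            acc = evaluate_accuracy(model, eval_corpus)
        timing = ideal_timing(model, eval_corpus)
        rows.append(
            {
                "interval_ms": interval,
                "effective_interval_ms": model.config.effective_interval_ms,
                "latency_ms": timing[0].latency_mean_ms,
                "jitter_ms": timing[0].jitter_ms,
                "tp_pct": float(acc.tp_pct[0]),
                "fp_pct": float(acc.fp_pct[0]),
            }
        )
    return pd.DataFrame(rows)
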