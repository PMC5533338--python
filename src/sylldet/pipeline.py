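"""End-to-end training: corpus in, ready-to-run detector model out.

Mirrors the offline phase of the original workflow: assemble the training
matrix from the aligned corpus, z-score each recognition window, fit and
apply the per-feature scaling, train the perceptron with early stopping,
compute the raw outputs over the full training corpus, and pick the
cost-optimal trigger threshold per syllable.  The returned model carries
everything the streaming detector needs.
"""

from __future__ import annotations

import numpy as np

from .frontend import FrameConfig, resolve_frame_config
from .model import DetectorModel
from .network import TrainConfig, TrainResult, train
from .synth import AnnotatedCorpus
from .thresholds import ClipOutputs, CostConfig, optimize_thresholds
from .training import build_training_set, fit_feature_norm, window_normalize

__all__ = ["train_detector"]


def train_detector(
    corpus: AnnotatedCorpus,
    frame_config: FrameConfig | None = None,
    *,
    fft_size: int = 256,
    frame_interval_ms: float = 1.5,
    band: tuple[float, float] = (1000.0, 8000.0),
    window_ms: float = 50.0,
    target_sd_ms: float = 2.0,
    train_config: TrainConfig | None = None,
    cost: CostConfig | None = None,
    debounce_ms: float = 100.0,
) -> tuple[DetectorModel, TrainResult]:
    """Train a detector on an annotated corpus with the default recipe.

    Either pass a resolved ``frame_config`` or the individual geometry
    arguments (defaults: 256-point FFT, 1.5 ms requested frame interval,
    1–8 kHz band, 50 ms recognition window).
    """
    if frame_config is None:
        frame_config = resolve_frame_config(
            fft_size=fft_size,
            requested_interval_ms=frame_interval_ms,
            sample_rate=corpus.sample_rate,
            band=band,
            window_ms=window_ms,
        )
    elif frame_config.sample_rate != corpus.sample_rate:
        raise ValueError(
            f"frame config at {frame_config.sample_rate} Hz, corpus at "
            f"{corpus.sample_rate} Hz"
        )
    train_config = train_config or TrainConfig()
    cost = cost or CostConfig()

    ts = build_training_set(corpus, frame_config, target_sd_ms=target_sd_ms)
    window_normalize(ts.X, out=ts.X)
    ts.stage = "window_normalized"
    norm = fit_feature_norm(ts.X)
    norm.apply(ts.X, out=ts.X)
    ts.stage = "feature_normalized"

    result = train(ts.X, ts.targets, train_config)

    # raw outputs over the full training corpus drive the threshold search
    from .network import forward

    outputs = np.empty((ts.n_columns, ts.n_targets))
    block = 65536
    for start in range(0, ts.n_columns, block):
        outputs[start : start + block] = forward(
            result.params, ts.X[start : start + block]
        )
    clips = _group_outputs(ts, outputs, corpus)
    thresholds = optimize_thresholds(clips, cost)

    model = DetectorModel(
        params=result.params,
        feature_norm=norm,
        config=frame_config,
        thresholds=thresholds,
        cost=cost,
        debounce_ms=debounce_ms,
        target_sd_ms=target_sd_ms,
        train_corpus_id=corpus.corpus_id,
    )
    return model, result


def _group_outputs(ts, outputs, corpus) -> list[ClipOutputs]:
    """Regroup training-matrix columns into per-clip output traces."""
    clips = []
    for is_song in (True, False):
        n_clips = len(corpus.songs) if is_song else len(corpus.nonsong)
        for i in range(n_clips):
            mask = (ts.clip_kind == is_song) & (ts.clip_index == i)
            events = None
            if is_song:
                events = [
                    np.atleast_1d(corpus.canonical_times[i, k])
                    for k in range(corpus.n_targets)
                ]
            clips.append(
                ClipOutputs(
                    times_ms=ts.time_ms[mask],
                    outputs=outputs[mask],
                    is_song=is_song,
                    events=events,
                )
            )
    return clips
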