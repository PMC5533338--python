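"""Per-frame error accounting and cost-optimal trigger thresholds.

A detection threshold θ_k per target syllable is chosen to minimize
FP(θ) + C_n·FN(θ) over the training corpus, where C_n is the relative cost
of a false negative (default 1) and accuracy is scored per frame: an event
at t* counts as detected if at least one frame within ±Δt (default 10 ms)
has output above θ; every above-threshold frame outside all event windows
counts as one false-positive frame.  The raw (un-de-bounced) outputs are
used throughout.

The cost is piecewise constant in θ, changing only when θ crosses an
observed output value, so the exact optimum is found on the grid of
midpoints between consecutive sorted unique outputs (plus one point above
the maximum).  Ties are broken toward the largest minimizing θ — flat
regions of the cost are common, and a higher threshold is conservative
against false positives on unseen data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CostConfig",
    "ClipOutputs",
    "ErrorCounts",
    "count_errors",
    "optimal_threshold",
    "optimize_thresholds",
]


@dataclass(frozen=True)
class CostConfig:
    """``false_negative_cost`` is C_n; ``accept_window_ms`` the half-window Δt."""

    false_negative_cost: float = 1.0
    accept_window_ms: float = 10.0

    def __post_init__(self):
        if self.false_negative_cost <= 0:
            raise ValueError("false_negative_cost must be positive")
        if self.accept_window_ms < 0:
            raise ValueError("accept_window_ms must be >= 0")


@dataclass
class ClipOutputs:
    """Raw network outputs for every usable frame of one clip.

    ``events`` holds, per target syllable, the canonical event times (ms)
    occurring in this clip; ``None`` or empty arrays for non-song clips.
    """

    times_ms: np.ndarray  # (n_frames,)
    outputs: np.ndarray  # (n_frames, n_targets)
    is_song: bool
    events: list[np.ndarray] | None = None

    def events_for(self, syllable: int) -> np.ndarray:
        if self.events is None:
            return np.empty(0)
        return np.atleast_1d(np.asarray(self.events[syllable], dtype=np.float64))


@dataclass
class ErrorCounts:
    fp: int
    fn: int
    tp: int
    n_events: int = 0
    n_negative_frames: int = 0

    def cost(self, cost: CostConfig) -> float:
        return self.fp + cost.false_negative_cost * self.fn


def _clip_errors(
    times: np.ndarray,
    out: np.ndarray,
    events: np.ndarray,
    threshold: float,
    half_window: float,
) -> tuple[int, int, int, int]:
    """(fp, fn, tp, n_negative_frames) for one clip and one syllable.

    Above-threshold frames are assigned to event windows greedily in time
    order, each frame satisfying at most one event (this matters only when
    event windows overlap).
    """
    above = times[out > threshold]
    in_any_window = np.zeros(len(above), dtype=bool)
    for t_star in events:
        in_any_window |= np.abs(above - t_star) <= half_window
    fp = int(len(above) - in_any_window.sum())

    used = np.zeros(len(above), dtype=bool)
    tp = 0
    for t_star in np.sort(events):
        ok = np.flatnonzero(~used & (np.abs(above - t_star) <= half_window))
        if len(ok):
            used[ok[0]] = True
            tp += 1
    fn = len(events) - tp

    neg = np.ones(len(times), dtype=bool)
    for t_star in events:
        neg &= np.abs(times - t_star) > half_window
    return fp, fn, tp, int(neg.sum())


def count_errors(
    clips: list[ClipOutputs],
    threshold: float,
    cost: CostConfig,
    syllable: int = 0,
) -> ErrorCounts:
    """Per-frame FP/FN/TP counts over a corpus at a fixed threshold."""
    total = ErrorCounts(0, 0, 0)
    for clip in clips:
        events = clip.events_for(syllable)
        fp, fn, tp, n_neg = _clip_errors(
            clip.times_ms, clip.outputs[:, syllable], events,
            threshold, cost.accept_window_ms,
        )
        total.fp += fp
        total.fn += fn
        total.tp += tp
        total.n_events += len(events)
        total.n_negative_frames += n_neg
    return total


def _candidate_grid(values: np.ndarray) -> np.ndarray:
    u = np.unique(values)
    if len(u) == 1:
        return np.array([u[0] - 1.0, u[0] + 1.0])
    mid = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[u[0] - 1.0], mid, [u[-1] + 1.0]])


def _windows_overlap(clips: list[ClipOutputs], syllable: int, half: float) -> bool:
    for c in clips:
        ev = np.sort(c.events_for(syllable))
        if len(ev) > 1 and np.any(np.diff(ev) <= 2 * half):
            return True
    return False


def optimal_threshold(
    clips: list[ClipOutputs],
    cost: CostConfig | None = None,
    syllable: int = 0,
) -> float:
    """Cost-minimizing threshold for one syllable (largest minimizer).

    Uses an O(n log n) sorted-array scan when event windows do not overlap
    (the cost then decomposes into per-event window maxima plus
    out-of-window frame counts); falls back to evaluating
    :func:`count_errors` at every candidate otherwise.  The two paths agree
    exactly because the cost is piecewise constant between observed output
    values.
    """
    cost = cost or CostConfig()
    half = cost.accept_window_ms
    all_out = np.concatenate([c.outputs[:, syllable] for c in clips])
    if sum(len(c.events_for(syllable)) for c in clips) == 0:
        raise ValueError("threshold optimization needs at least one event")
    cand = _candidate_grid(all_out)

    if not _windows_overlap(clips, syllable, half):
        window_max, outside = [], []
        for c in clips:
            out = c.outputs[:, syllable]
            ev = c.events_for(syllable)
            in_any = np.zeros(len(c.times_ms), dtype=bool)
            for t_star in ev:
                in_win = np.abs(c.times_ms - t_star) <= half
                # an event whose window holds no frame can never be detected
                window_max.append(out[in_win].max() if in_win.any() else -np.inf)
                in_any |= in_win
            outside.append(out[~in_any])
        wmax = np.sort(window_max)
        outs = np.sort(np.concatenate(outside))
        fp = len(outs) - np.searchsorted(outs, cand, side="right")
        fn = np.searchsorted(wmax, cand, side="right")
        costs = fp + cost.false_negative_cost * fn
    else:
        costs = np.array(
            [count_errors(clips, th, cost, syllable).cost(cost) for th in cand]
        )
    best = costs.min()
    return float(cand[np.flatnonzero(costs == best)[-1]])


def optimize_thresholds(
    clips: list[ClipOutputs], cost: CostConfig | None = None
) -> np.ndarray:
    """Optimal threshold per target syllable."""
    n_targets = clips[0].outputs.shape[1]
    return np.array([optimal_threshold(clips, cost, k) for k in range(n_targets)])
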