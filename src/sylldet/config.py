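"""One defaults-first configuration file for the whole pipeline.

Every command reads the same YAML document (all keys optional — the
defaults are the recommended operating point: 256-point FFT, Hamming
window, 1.5 ms frame interval, 50 ms recognition window, 1–8 kHz band,
2 ms target smoothing, Δt = 10 ms, C_n = 1, 100 ms de-bounce, 4 hidden
units per syllable).  Unknown keys are rejected rather than ignored, so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineConfig", "FrameSection", "TrainSection", "CostSection",
           "CorpusSection"]


def _from_mapping(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {where!r}; "
            f"known keys: {sorted(known)}"
        )
    return cls(**data)


@dataclass
class FrameSection:
    fft_size: int = 256
    frame_interval_ms: float = 1.5
    window_ms: float = 50.0
    band_lo_hz: float = 1000.0
    band_hi_hz: float = 8000.0


@dataclass
class TrainSection:
    hidden_per_syllable: int = 4
    train_frac: float = 0.8
    max_iter: int = 400
    patience: int = 30
    target_sd_ms: float = 2.0


@dataclass
class CostSection:
    false_negative_cost: float = 1.0
    accept_window_ms: float = 10.0


@dataclass
class CorpusSection:
    n_songs: int = 1000
    n_nonsong: int = 1000
    onset_jitter_sd_ms: float = 2.0
    amplitude_jitter_sd: float = 0.1
    noise_snr_db: float = 25.0
    sample_rate: float = 44100.0
    kind: str = "song"  # "song" or "delta"
    delta_target_offset_ms: float = 5.0


@dataclass
class PipelineConfig:
    frame: FrameSection = field(default_factory=FrameSection)
    train: TrainSection = field(default_factory=TrainSection)
    cost: CostSection = field(default_factory=CostSection)
    corpus: CorpusSection = field(default_factory=CorpusSection)
    debounce_ms: float = 100.0
    seed: int = 0

    @staticmethod
    def load(path: str | os.PathLike | None) -> "PipelineConfig":
        if path is None:
            return PipelineConfig()
        with open(os.fspath(path)) as fh:
            data = yaml.safe_load(fh) or {}
        return PipelineConfig.from_dict(data)

    @staticmethod
    def from_dict(data: dict) -> "PipelineConfig":
        sections = {"frame": FrameSection, "train": TrainSection,
                    "cost": CostSection, "corpus": CorpusSection}
        scalars = {"debounce_ms", "seed"}
        unknown = set(data) - set(sections) - scalars
        if unknown:
            raise ValueError(
                f"unknown top-level config key(s) {sorted(unknown)}; known: "
                f"{sorted(set(sections) | scalars)}"
            )
        kwargs = {
            name: _from_mapping(cls, data.get(name, {}) or {}, name)
            for name, cls in sections.items()
        }
        return PipelineConfig(
            **kwargs,
            debounce_ms=float(data.get("debounce_ms", 100.0)),
            seed=int(data.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def dump(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
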