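"""The trained detector bundle: network, normalization, thresholds, geometry.

Everything the runtime detector needs lives in one self-describing ``.npz``
container with a format version: the weight matrices, the per-feature
normalization, the per-syllable trigger thresholds, the frame configuration
that produced them (a model is only valid at the sample rate and hop it was
trained with), the de-bounce interval, and the identity of the trainer.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .frontend import FrameConfig
from .network import NetworkParams, TRAINER_NAME, forward
from .thresholds import CostConfig
from .training import FeatureNorm

__all__ = ["DetectorModel", "save_model", "load_model", "ModelFormatError"]

FORMAT_VERSION = 1


class ModelFormatError(ValueError):
    """Model file is missing, truncated, corrupted, or an unknown version."""


@dataclass
class DetectorModel:
    params: NetworkParams
    feature_norm: FeatureNorm
    config: FrameConfig
    thresholds: np.ndarray  # (n_targets,)
    cost: CostConfig = field(default_factory=CostConfig)
    debounce_ms: float = 100.0
    target_sd_ms: float = 2.0
    train_corpus_id: str = ""
    trainer: str = TRAINER_NAME

    @property
    def n_targets(self) -> int:
        return len(self.thresholds)

    @property
    def sample_rate(self) -> float:
        return self.config.sample_rate

    def forward(self, xi_checked: np.ndarray) -> np.ndarray:
        """Network output for already feature-normalized input."""
        return forward(self.params, xi_checked)

    def evaluate_window(self, xi_raw: np.ndarray) -> np.ndarray:
        """Both normalization stages plus the forward pass, on raw power
        recognition vectors (single or batch)."""
        from .training import window_normalize

        xi = window_normalize(xi_raw)
        return self.forward(self.feature_norm.apply(xi, out=xi))


def save_model(model: DetectorModel, path: str | os.PathLike) -> None:
    """Write the model to a single ``.npz`` file (lossless round-trip)."""
    header = {
        "format_version": FORMAT_VERSION,
        "frame_config": model.config.to_dict(),
        "cost": {
            "false_negative_cost": model.cost.false_negative_cost,
            "accept_window_ms": model.cost.accept_window_ms,
        },
        "debounce_ms": model.debounce_ms,
        "target_sd_ms": model.target_sd_ms,
        "train_corpus_id": model.train_corpus_id,
        "trainer": model.trainer,
    }
    with open(os.fspath(path), "wb") as fh:
        np.savez(
            fh,
            header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
            W0=model.params.W0, b0=model.params.b0,
            W1=model.params.W1, b1=model.params.b1,
            mu=model.feature_norm.mu, sigma=model.feature_norm.sigma,
            thresholds=np.asarray(model.thresholds, dtype=np.float64),
        )


def load_model(path: str | os.PathLike) -> DetectorModel:
    """Read a model written by :func:`save_model`; explicit errors on
    truncation, corruption, or version mismatch."""
    try:
        with np.load(os.fspath(path)) as data:
            header = json.loads(bytes(data["header"]).decode())
            arrays = {k: data[k] for k in
                      ("W0", "b0", "W1", "b1", "mu", "sigma", "thresholds")}
    except ModelFormatError:
        raise
    except Exception as exc:
        raise ModelFormatError(
            f"cannot read detector model {path!r}: {exc}"
        ) from exc
    version = header.get("format_version")
    if version != FORMAT_VERSION:
        raise ModelFormatError(
            f"model {path!r} has format version {version}, "
            f"this build reads version {FORMAT_VERSION}"
        )
    config = FrameConfig.from_dict(header["frame_config"])
    params = NetworkParams(arrays["W0"], arrays["b0"], arrays["W1"], arrays["b1"])
    if params.W0.shape[1] != config.input_dim:
        raise ModelFormatError(
            f"model {path!r}: weight shape {params.W0.shape} inconsistent with "
            f"frame configuration input dimension {config.input_dim}"
        )
    return DetectorModel(
        params=params,
        feature_norm=FeatureNorm(mu=arrays["mu"], sigma=arrays["sigma"]),
        config=config,
        thresholds=arrays["thresholds"],
        cost=CostConfig(**header["cost"]),
        debounce_ms=float(header["debounce_ms"]),
        target_sd_ms=float(header.get("target_sd_ms", 2.0)),
        train_corpus_id=header.get("train_corpus_id", ""),
        trainer=header.get("trainer", "unknown"),
    )
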