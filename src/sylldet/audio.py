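"""WAV reading/writing for mono clips and stereo ground-truth test files.

Samples are represented in memory as float64 in [-1, 1].  Integer PCM
(16/24/32-bit) is scaled by the magnitude of its most negative code on read;
files are written as float32 (or PCM16 on request).  Resampling is out of
scope: callers must check the header rate against the rate a model expects.
"""

from __future__ import annotations

import os

import numpy as np
from scipy.io import wavfile

__all__ = ["read_wav", "write_wav", "SampleRateMismatch"]


class SampleRateMismatch(ValueError):
    """Audio sample rate differs from the rate the detector was trained at."""


_INT_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31,
              np.dtype(np.uint8): 2**7}


def read_wav(path: str | os.PathLike) -> tuple[np.ndarray, int]:
    """Read a WAV file; returns ``(samples, sample_rate)``.

    Mono files yield a 1-D float64 array; stereo files an ``(n, 2)`` array.
    """
    try:
        rate, data = wavfile.read(os.fspath(path))
    except Exception as exc:  # surface the offending path
        raise OSError(f"cannot read WAV file {path!r}: {exc}") from exc
    if data.dtype in _INT_SCALE:
        scale = _INT_SCALE[data.dtype]
        if data.dtype == np.dtype(np.uint8):  # unsigned 8-bit is offset binary
            samples = (data.astype(np.float64) - 128.0) / scale
        else:
            samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    return samples, int(rate)


def write_wav(
    path: str | os.PathLike,
    samples: np.ndarray,
    sample_rate: int,
    dtype: str = "float32",
) -> None:
    """Write mono (1-D) or stereo ``(n, 2)`` samples to a WAV file."""
    samples = np.asarray(samples)
    if dtype == "float64":
        out = samples.astype(np.float64)
    elif dtype == "float32":
        out = samples.astype(np.float32)
    elif dtype == "int16":
        out = np.clip(np.round(samples * 2**15), -(2**15), 2**15 - 1).astype(
            np.int16
        )
    else:
        raise ValueError(f"unsupported output dtype {dtype!r}")
    try:
        wavfile.write(os.fspath(path), int(sample_rate), out)
    except Exception as exc:
        raise OSError(f"cannot write WAV file {path!r}: {exc}") from exc
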