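"""Mono WAV reading and writing with exact round-trip semantics.

Vibration recordings in this domain are single-channel by construction
(one piezoelectric probe per trunk), so only mono files are accepted.
Two RIFF dialects are supported: 16-bit PCM (samples scaled by 1/32768 on
read) and IEEE float32 (bit-exact round trip).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

__all__ = [
    "Waveform",
    "read_wav",
    "write_wav",
    "WavError",
    "MultiChannelError",
    "UnsupportedEncodingError",
    "SampleRangeError",
]

PCM16_SCALE = 32768.0


class WavError(ValueError):
    """Base class for WAV I/O failures."""


class MultiChannelError(WavError):
    """File has more than one channel; only mono is supported."""


class UnsupportedEncodingError(WavError):
    """Sample encoding other than PCM16 / IEEE float32."""


class SampleRangeError(WavError):
    """Sample outside [-1, 1] cannot be written as PCM16."""


@dataclass(frozen=True)
class Waveform:
    """A mono sample sequence with its sample rate in Hz."""

    samples: np.ndarray
    sample_rate: int = 32000

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not (isinstance(self.sample_rate, (int, np.integer)) and self.sample_rate > 0):
            raise ValueError("sample_rate must be a positive integer")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def __len__(self) -> int:
        return self.samples.size

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


def read_wav(path: str | os.PathLike) -> Waveform:
    """Read a mono WAV file.

    PCM16 samples are scaled by 1/32768; float32 samples are taken as-is.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    MultiChannelError
        If the file has more than one channel.
    UnsupportedEncodingError
        If the sample format is neither PCM16 nor IEEE float32.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(path)
    except ValueError as e:
        raise UnsupportedEncodingError(str(e)) from e
    if data.ndim != 1:
        raise MultiChannelError(f"{path}: {data.shape[1]} channels, mono required")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / PCM16_SCALE
    elif data.dtype == np.float32:
        samples = data.astype(np.float64)
    else:
        raise UnsupportedEncodingError(f"{path}: dtype {data.dtype} unsupported")
    return Waveform(samples, int(rate))


def write_wav(path: str | os.PathLike, w: Waveform, encoding: str = "float32") -> None:
    """Write *w* to *path* as ``pcm16`` or ``float32``.

    PCM16 writing raises :class:`SampleRangeError` for samples outside
    [-1, 1] rather than clipping, so mixtures that exceed full scale are
    never silently corrupted.
    """
    if encoding == "float32":
        wavfile.write(path, w.sample_rate, w.samples.astype(np.float32))
    elif encoding == "pcm16":
        if np.any(np.abs(w.samples) > 1.0):
            raise SampleRangeError(
                f"peak {np.max(np.abs(w.samples)):.4f} exceeds PCM16 full scale"
            )
        ints = np.clip(np.round(w.samples * PCM16_SCALE), -32768, 32767)
        wavfile.write(path, w.sample_rate, ints.astype(np.int16))
    else:
        raise UnsupportedEncodingError(f"unknown encoding {encoding!r}")
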