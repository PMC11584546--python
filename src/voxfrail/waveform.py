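"""Mono waveform container and WAV I/O.

The acoustic stages all consume :class:`Waveform`: a float array of samples
in [-1, 1] together with its sampling rate and optional subject/repeat
identity. WAV files are read and written with :mod:`scipy.io.wavfile`;
integer PCM is rescaled to float on read, stereo inputs are downmixed to
mono with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .exceptions import ValidationError

__all__ = ["Waveform", "read_wav", "write_wav"]


@dataclass
class Waveform:
    """A mono audio signal.

    Parameters
    ----------
    samples : ndarray
        Amplitude sequence (dimensionless). Finite, non-empty, 1-D.
    sample_rate_hz : float
        Sampling rate, > 0.
    subject_id : str, optional
        Identifier of the recorded subject.
    repeat_index : int, optional
        1-based repeat number within the subject's session (1..3).
    """

    samples: np.ndarray
    sample_rate_hz: float
    subject_id: str | None = None
    repeat_index: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError("waveform must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("waveform contains non-finite samples")
        if not (self.sample_rate_hz > 0):
            raise ValidationError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def remove_dc(self) -> "Waveform":
        """Return a copy with the mean subtracted (protects zero-crossing counts)."""
        return replace(self, samples=self.samples - self.samples.mean())

    def normalized(self) -> "Waveform":
        """Return a copy scaled to peak |1| (no-op on an all-zero signal)."""
        peak = np.max(np.abs(self.samples))
        if peak == 0:
            return replace(self, samples=self.samples.copy())
        return replace(self, samples=self.samples / peak)

    def slice_seconds(self, start_s: float, end_s: float) -> "Waveform":
        i0 = max(0, int(round(start_s * self.sample_rate_hz)))
        i1 = min(self.n_samples, int(round(end_s * self.sample_rate_hz)))
        if i1 <= i0:
            raise ValidationError("empty slice requested")
        return replace(self, samples=self.samples[i0:i1].copy())


def read_wav(path: str | Path, subject_id: str | None = None,
             repeat_index: int | None = None) -> Waveform:
    """Read a WAV file into a :class:`Waveform`.

    Integer PCM is rescaled to [-1, 1]; multi-channel audio is averaged to
    mono with a logged warning.
    """
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:
        warnings.warn(f"{path}: stereo input downmixed to mono", stacklevel=2)
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(max(abs(np.iinfo(data.dtype).min), np.iinfo(data.dtype).max))
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return Waveform(data, float(rate), subject_id=subject_id, repeat_index=repeat_index)


def write_wav(path: str | Path, w: Waveform) -> None:
    """Write a waveform as 32-bit float mono WAV."""
    wavfile.write(str(path), int(round(w.sample_rate_hz)),
                  w.samples.astype(np.float32))
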