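"""The four sustained-vowel acoustic parameters A1-A4.

A1 — mean zero-crossing rate: per frame, the number of sign changes between
consecutive samples divided by the frame length in samples, averaged over
frames. Dimensionless in [0, 1]; for a pure tone of frequency f it equals
2 f / fs.

A2 — local peak/valley variation: per frame, take the largest local-maximum
amplitude P_i and the smallest local-minimum amplitude V_i; across frames
compute the mean absolute deviations D_P and D_V of those extremum series
from their means. A2 = 100 * (D_P/|mean P| + D_V/|mean V|) / 2 (percent of
the mean extremum amplitude) — a shimmer-like amplitude-stability measure.
A raw-amplitude variant (no normalization) is available via
``A2Config(relative=False)``.

A3 — formant-frequency variation: frame-wise F1/F2 estimates by
linear-prediction spectral analysis (anti-aliased downsampling to ~11 kHz,
pre-emphasis, autocorrelation LP, polynomial roots filtered by bandwidth
and minimum frequency; the two lowest surviving resonances are F1 < F2).
A3 = (MAD(F1) + MAD(F2)) / 2 in Hz, where MAD is the mean absolute
deviation from the mean.

A4 — low-frequency spectral energy ratio: fraction of averaged-periodogram
power at or below the end frequency (default 800 Hz) relative to total
power up to Nyquist. Dimensionless in [0, 1].

All four are deterministic given the waveform and configuration, and
invariant to amplitude scaling of the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import numpy as np
from scipy import linalg as sla
from scipy import signal as sps

from .exceptions import (InsufficientDataError, UndefinedRatioError,
                         ValidationError)
from .waveform import Waveform

__all__ = [
    "FrameConfig",
    "A2Config",
    "A3Config",
    "A4Config",
    "compute_a1",
    "compute_a2",
    "compute_a3",
    "compute_a4",
    "extract_features",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("A1", "A2", "A3", "A4")


@dataclass(frozen=True)
class FrameConfig:
    """Short-time framing for A1/A2 (20 ms frames, 10 ms hop by default)."""

    frame_length_s: float = 0.020
    hop_length_s: float = 0.010
    window: str = "hamming"

    def __post_init__(self) -> None:
        if not (0 < self.hop_length_s <= self.frame_length_s):
            raise ValidationError("need 0 < hop_length_s <= frame_length_s")


@dataclass(frozen=True)
class A2Config(FrameConfig):
    #: normalize deviations by the mean extremum amplitude (percent scale);
    #: False gives the raw-amplitude variant
    relative: bool = True


@dataclass(frozen=True)
class A3Config:
    """Linear-prediction formant tracking settings."""

    frame_length_s: float = 0.030
    hop_length_s: float = 0.010
    preemphasis: float = 0.97
    lpc_order: int = 12
    target_rate_hz: float = 11025.0
    min_formant_hz: float = 90.0
    max_bandwidth_hz: float = 400.0


@dataclass(frozen=True)
class A4Config:
    end_frequency_hz: float = 800.0
    segment_length: int = 4096
    overlap: float = 0.5
    window: str = "hann"


def _frames(x: np.ndarray, fs: float, frame_s: float, hop_s: float) -> np.ndarray:
    frame = int(round(frame_s * fs))
    hop = max(1, int(round(hop_s * fs)))
    if frame < 2 or x.size < frame:
        raise InsufficientDataError("signal shorter than one analysis frame")
    view = np.lib.stride_tricks.sliding_window_view(x, frame)
    return view[::hop]


def compute_a1(w: Waveform, cfg: FrameConfig = FrameConfig()) -> float:
    """Mean zero-crossing rate (crossings per sample), in [0, 1].

    Each frame counts sign changes over exactly ``frame`` sample intervals
    (the window extends one sample past the frame end when available), so
    the frame average is unbiased even when the hop is phase-locked to the
    signal period.
    """
    x = w.samples - w.samples.mean()
    fs = w.sample_rate_hz
    frame = int(round(cfg.frame_length_s * fs))
    hop = max(1, int(round(cfg.hop_length_s * fs)))
    if frame < 2 or x.size < frame:
        raise InsufficientDataError("signal shorter than one analysis frame")
    width = frame + 1 if x.size > frame else frame
    view = np.lib.stride_tricks.sliding_window_view(x, width)[::hop]
    s = view >= 0
    crossings = np.sum(s[:, 1:] != s[:, :-1], axis=1)
    return float(np.mean(crossings / frame))


def _frame_extrema(frame: np.ndarray) -> tuple[float, float] | None:
    """Largest local-maximum and smallest local-minimum amplitude, or None."""
    peaks, _ = sps.find_peaks(frame)
    valleys, _ = sps.find_peaks(-frame)
    if peaks.size == 0 or valleys.size == 0:
        return None
    return float(frame[peaks].max()), float(frame[valleys].min())


def compute_a2(w: Waveform, cfg: A2Config = A2Config()) -> float:
    """Peak/valley amplitude variation across frames (% when relative)."""
    x = w.samples - w.samples.mean()
    frames = _frames(x, w.sample_rate_hz, cfg.frame_length_s, cfg.hop_length_s)
    if frames.shape[0] < 2:
        raise InsufficientDataError("A2 needs at least two frames")
    peaks, valleys = [], []
    skipped = 0
    for frame in frames:
        ext = _frame_extrema(frame)
        if ext is None:
            skipped += 1
            continue
        peaks.append(ext[0])
        valleys.append(ext[1])
    if skipped:
        warnings.warn(f"A2: {skipped} frame(s) without interior extrema skipped",
                      stacklevel=2)
    if len(peaks) < 2:
        raise InsufficientDataError("A2: fewer than two frames with extrema")
    p = np.asarray(peaks)
    v = np.asarray(valleys)
    d_p = np.mean(np.abs(p - p.mean()))
    d_v = np.mean(np.abs(v - v.mean()))
    if not cfg.relative:
        return float((d_p + d_v) / 2.0)
    if p.mean() == 0 or v.mean() == 0:
        raise UndefinedRatioError("A2: mean extremum amplitude is zero")
    return float(100.0 * (d_p / abs(p.mean()) + d_v / abs(v.mean())) / 2.0)


def _lpc_roots_formants(frame: np.ndarray, fs: float, cfg: A3Config
                        ) -> list[float]:
    """Candidate resonance frequencies from autocorrelation LP of one frame."""
    order = cfg.lpc_order
    n = frame.size
    if n <= order + 1:
        return []
    r = np.correlate(frame, frame, mode="full")[n - 1: n + order]
    if r[0] <= 0:
        return []
    r = r / r[0]
    r[0] *= 1.0 + 1e-9  # ridge for numerical stability
    try:
        a = sla.solve_toeplitz((r[:-1], r[:-1]), -r[1:])
    except np.linalg.LinAlgError:
        return []
    poly = np.concatenate(([1.0], a))
    roots = np.roots(poly)
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * fs / (2.0 * np.pi)
    bws = -fs / np.pi * np.log(np.clip(np.abs(roots), 1e-12, None))
    keep = ((freqs > cfg.min_formant_hz)
            & (freqs < 0.95 * fs / 2.0)
            & (bws < cfg.max_bandwidth_hz))
    return sorted(freqs[keep].tolist())


def compute_a3(w: Waveform, cfg: A3Config = A3Config()) -> float:
    """Mean absolute deviation of frame-wise F1 and F2 from their means (Hz)."""
    x = w.samples - w.samples.mean()
    fs = w.sample_rate_hz
    if fs > cfg.target_rate_hz:
        frac = Fraction(int(round(cfg.target_rate_hz)),
                        int(round(fs))).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator)
        fs = fs * frac.numerator / frac.denominator
    x = np.append(x[0], x[1:] - cfg.preemphasis * x[:-1])

    frames = _frames(x, fs, cfg.frame_length_s, cfg.hop_length_s)
    window = np.hamming(frames.shape[1])
    f1_track, f2_track = [], []
    skipped = 0
    for frame in frames:
        cands = _lpc_roots_formants(frame * window, fs, cfg)
        if len(cands) < 2:
            skipped += 1
            continue
        f1_track.append(cands[0])
        f2_track.append(cands[1])
    if skipped:
        warnings.warn(f"A3: {skipped} frame(s) with <2 formant candidates skipped",
                      stacklevel=2)
    if len(f1_track) < 2:
        raise InsufficientDataError("A3: fewer than two valid formant frames")
    f1 = np.asarray(f1_track)
    f2 = np.asarray(f2_track)
    mad = lambda t: float(np.mean(np.abs(t - t.mean())))
    return (mad(f1) + mad(f2)) / 2.0


def compute_a4(w: Waveform, cfg: A4Config = A4Config(),
               end_frequency_hz: float | None = None) -> float:
    """Spectral energy ratio below the end frequency, in [0, 1].

    The power spectrum is an averaged periodogram (Welch) of the whole
    trimmed utterance; the bin at exactly the end frequency counts toward
    the numerator.
    """
    fend = cfg.end_frequency_hz if end_frequency_hz is None else float(end_frequency_hz)
    if not (0 < fend <= w.sample_rate_hz / 2.0):
        raise ValidationError("end frequency must be in (0, Nyquist]")
    x = w.samples - w.samples.mean()
    nper = min(cfg.segment_length, x.size)
    freqs, pxx = sps.welch(x, fs=w.sample_rate_hz, window=cfg.window,
                           nperseg=nper, noverlap=int(cfg.overlap * nper))
    total = float(pxx.sum())
    if total <= 0:
        raise UndefinedRatioError("A4: zero total spectral energy")
    return float(pxx[freqs <= fend].sum() / total)


def extract_features(w: Waveform,
                     frame_cfg: FrameConfig = FrameConfig(),
                     a2_cfg: A2Config | None = None,
                     a3_cfg: A3Config = A3Config(),
                     a4_cfg: A4Config = A4Config()) -> dict[str, float]:
    """Compute all four parameters for one trimmed recording."""
    if a2_cfg is None:
        a2_cfg = A2Config(frame_length_s=frame_cfg.frame_length_s,
                          hop_length_s=frame_cfg.hop_length_s,
                          window=frame_cfg.window)
    return {
        "A1": compute_a1(w, frame_cfg),
        "A2": compute_a2(w, a2_cfg),
        "A3": compute_a3(w, a3_cfg),
        "A4": compute_a4(w, a4_cfg),
    }
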