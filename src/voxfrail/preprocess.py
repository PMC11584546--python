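"""Recording QC: endpoint detection, duration gate, repeat-variability rule.

The pipeline accepts exactly three repeats of the sustained vowel per
subject. Each repeat is trimmed to its voiced portion with an energy +
zero-crossing double-threshold endpoint detector, gated on trimmed duration
(0.8-1.2 s inclusive), and the four acoustic parameters are computed per
repeat. A parameter is accepted for a subject only when its coefficient of
variation across the three repeats is below 15%; the accepted value is the
mean of the three repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .exceptions import InsufficientDataError, NoSpeechError, ValidationError
from .waveform import Waveform

__all__ = [
    "EndpointConfig",
    "RecordingQC",
    "QCReport",
    "detect_endpoints",
    "validate_duration",
    "select_repeats",
    "PARAMETER_NAMES",
]

PARAMETER_NAMES = ("A1", "A2", "A3", "A4")

#: duration gate (inclusive): "shorter than 0.8 s or longer than 1.2 s" is withdrawn
DURATION_MIN_S = 0.8
DURATION_MAX_S = 1.2

#: repeat variability rule: CV must be strictly below this many percent
VARIABILITY_THRESHOLD_PCT = 15.0

N_REPEATS = 3


@dataclass(frozen=True)
class EndpointConfig:
    """Double-threshold endpoint detector settings (Rabiner-style)."""

    frame_length_s: float = 0.020
    hop_length_s: float = 0.010
    noise_floor_s: float = 0.100    # leading span used to estimate the noise floor
    upper_frac: float = 0.10        # upper energy threshold, fraction of dynamic range
    lower_frac: float = 0.02        # lower energy threshold for boundary walk-back
    zcr_refine_s: float = 0.250     # how far boundaries may be extended by the ZCR test
    zcr_threshold: float = 0.25     # crossings per sample marking unvoiced speech

    def __post_init__(self) -> None:
        if not (0 < self.hop_length_s <= self.frame_length_s):
            raise ValidationError("need 0 < hop <= frame length")


@dataclass
class RecordingQC:
    """Per-recording trim/duration outcome."""

    repeat_index: int | None
    trimmed_duration_s: float
    duration_pass: bool
    reason: str = ""


@dataclass
class QCReport:
    """Per-subject QC outcome.

    ``per_parameter_cv_pct`` maps each parameter to its percent CV across
    repeats (NaN when undefined); ``accepted_values`` holds the 3-repeat
    mean where ``variability_pass`` is true and NaN elsewhere.
    """

    subject_id: str | None = None
    recordings: list[RecordingQC] = field(default_factory=list)
    per_parameter_cv_pct: dict[str, float] = field(default_factory=dict)
    variability_pass: dict[str, bool] = field(default_factory=dict)
    accepted_values: dict[str, float] = field(default_factory=dict)
    reasons: list[str] = field(default_factory=list)


def _frame_energies(x: np.ndarray, frame: int, hop: int) -> np.ndarray:
    n_frames = 1 + max(0, (x.size - frame)) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    return np.mean(frames ** 2, axis=1)


def _frame_zcr(x: np.ndarray, frame: int, hop: int) -> np.ndarray:
    s = x >= 0
    changes = (s[1:] != s[:-1]).astype(np.float64)
    n_frames = 1 + max(0, (x.size - frame)) // hop
    out = np.empty(n_frames)
    for i in range(n_frames):
        seg = changes[i * hop: i * hop + frame - 1]
        out[i] = seg.sum() / frame
    return out


def detect_endpoints(w: Waveform, cfg: EndpointConfig = EndpointConfig()) -> Waveform:
    """Trim leading and trailing non-speech from a recording.

    Short-time energy thresholds are set relative to a noise floor taken
    from the first ``noise_floor_s`` of the signal: the voiced region is the
    span of frames exceeding the upper threshold, extended outward to the
    last frames above the lower threshold, then optionally extended further
    over high-zero-crossing (unvoiced) frames near the boundaries. Raises
    :class:`NoSpeechError` if no frame exceeds the upper threshold.
    """
    x = w.samples - w.samples.mean()
    fs = w.sample_rate_hz
    frame = max(2, int(round(cfg.frame_length_s * fs)))
    hop = max(1, int(round(cfg.hop_length_s * fs)))
    if x.size < frame:
        raise InsufficientDataError("signal shorter than one analysis frame")

    energy = _frame_energies(x, frame, hop)
    if float(energy.max()) <= 1e-12:
        raise NoSpeechError("no frame exceeds the speech threshold")
    n_noise = max(1, int(round(cfg.noise_floor_s * fs / hop)))
    # noise floor: leading-span mean, but never above the global minimum
    # (a fully voiced input has no leading silence to estimate from)
    e_min = float(min(energy[:n_noise].mean(), energy.min()))
    e_max = float(energy.max())
    upper = e_min + cfg.upper_frac * (e_max - e_min)
    lower = e_min + cfg.lower_frac * (e_max - e_min)

    above = np.flatnonzero(energy >= upper)
    if above.size == 0:
        raise NoSpeechError("no frame exceeds the speech threshold")
    start_f, end_f = int(above[0]), int(above[-1])
    while start_f > 0 and energy[start_f - 1] > lower:
        start_f -= 1
    while end_f < energy.size - 1 and energy[end_f + 1] > lower:
        end_f += 1

    # zero-crossing refinement: pull in adjacent unvoiced (fricative-like)
    # frames that combine a high crossing rate with above-floor energy;
    # the energy condition keeps room noise (high ZCR, floor energy) out
    if cfg.zcr_refine_s > 0:
        zcr = _frame_zcr(x, frame, hop)
        reach = max(1, int(round(cfg.zcr_refine_s * fs / hop)))
        f = start_f
        while (f > 0 and start_f - f < reach
               and zcr[f - 1] >= cfg.zcr_threshold and energy[f - 1] > lower):
            f -= 1
        start_f = f
        f = end_f
        while (f < zcr.size - 1 and f - end_f < reach
               and zcr[f + 1] >= cfg.zcr_threshold and energy[f + 1] > lower):
            f += 1
        end_f = f

    i0 = start_f * hop
    i1 = min(x.size, end_f * hop + frame)
    return replace(w, samples=w.samples[i0:i1].copy())


def validate_duration(w: Waveform, min_s: float = DURATION_MIN_S,
                      max_s: float = DURATION_MAX_S) -> bool:
    """Duration gate on a trimmed recording: inclusive at both bounds."""
    return min_s <= w.duration_s <= max_s


def select_repeats(features_by_repeat: Sequence[Mapping[str, float]],
                   threshold_pct: float = VARIABILITY_THRESHOLD_PCT,
                   subject_id: str | None = None) -> QCReport:
    """Apply the 15% repeat-variability rule per parameter.

    For each of A1-A4 independently: CV% = 100 * population SD / mean over
    the three repeats. If CV% < ``threshold_pct`` the accepted value is the
    3-repeat mean; otherwise the parameter is marked missing (NaN). A
    parameter whose 3-repeat mean is zero has an undefined CV and is marked
    missing with a warning.
    """
    if len(features_by_repeat) != N_REPEATS:
        raise InsufficientDataError(
            f"need exactly {N_REPEATS} repeats, got {len(features_by_repeat)}")
    report = QCReport(subject_id=subject_id)
    for name in PARAMETER_NAMES:
        vals = np.array([float(f[name]) for f in features_by_repeat])
        if not np.all(np.isfinite(vals)):
            raise ValidationError(f"{name}: non-finite repeat value")
        mean = vals.mean()
        if mean == 0:
            warnings.warn(f"{name}: repeat mean is zero, CV undefined; "
                          "parameter marked missing", stacklevel=2)
            report.per_parameter_cv_pct[name] = float("nan")
            report.variability_pass[name] = False
            report.accepted_values[name] = float("nan")
            report.reasons.append(f"{name}:cv_undefined")
            continue
        cv = 100.0 * vals.std(ddof=0) / abs(mean)
        ok = cv < threshold_pct
        report.per_parameter_cv_pct[name] = float(cv)
        report.variability_pass[name] = bool(ok)
        report.accepted_values[name] = float(mean) if ok else float("nan")
        if not ok:
            report.reasons.append(f"{name}:cv_{cv:.1f}pct")
    return report
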