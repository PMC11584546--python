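"""Synthetic sustained-vowel generator and synthetic cohort generator.

Audio side
----------
A source-filter synthesizer for a sustained /a/-like vowel. The glottal
source is the derivative of a Rosenberg flow pulse: each cycle the flow
rises (cosine ramp over two thirds of the open phase), falls back to zero
over the remaining third, and stays closed for the rest of the period. The
``open_quotient`` — the open fraction of the cycle — controls the spectral
tilt of the source: a longer open phase lowers the maximum flow declination
rate and concentrates energy in the first harmonic, raising the
low-frequency energy ratio (A4). The tilt is applied explicitly as a
one-pole low-pass on the source whose cutoff falls as the open quotient
rises (Klatt-style tilt control), so the knob acts monotonically even
where the raw pulse spectrum's notches would interact with individual
formants. Cycle-to-cycle
period (jitter) and amplitude (shimmer) perturbations are i.i.d. Gaussian,
truncated at ±3 SD so a perturbed period can never collapse. The source is
filtered through a cascade of second-order resonators at the formant
frequencies; F1 and F2 may drift sinusoidally (same phase) to create
formant-frequency variation (A3). Aspiration noise is added at a stated
SNR. The synthesizer generates 50 ms of warm-up signal and discards it so
the emitted waveform is steady state.

Cohort side
-----------
:func:`generate_cohort` draws per-subject clinical assessment items from
configurable distributions, scores the true frailty phenotypes with the
rule-based criteria, and then either

* mode ``"phenotype"`` — draws acoustic features A1–A4 conditionally on the
  true phenotype statuses (a known-truth table for the analysis stages), or
* mode ``"logistic"`` — draws features marginally and then draws a binary
  outcome from ``Bernoulli(logistic(intercept + sum(coef * feature)))``;
  this is the parameter-recovery harness for the association models.

Everything is reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import ConfigurationError, SizeError, ValidationError
from .phenotypes import AssessmentRecord, score_record
from .waveform import Waveform

__all__ = [
    "GlottalSourceParams",
    "VocalTractParams",
    "VowelSpec",
    "AssessmentDistributions",
    "FeatureLinkModel",
    "OutcomeLink",
    "CohortSpec",
    "CohortTables",
    "glottal_pulse_train",
    "synthesize_vowel",
    "generate_cohort",
]

#: hard budget on a single synthesis request (samples)
MAX_SAMPLES = 60 * 192_000

FEATURE_NAMES = ("A1", "A2", "A3", "A4")


# --------------------------------------------------------------------------
# parameter objects
# --------------------------------------------------------------------------

@dataclass
class GlottalSourceParams:
    """Voice-source parameters.

    f0 : fundamental frequency in Hz (> 0).
    jitter_pct : SD of the cycle-to-cycle period perturbation, % of the
        nominal period (0 <= jitter < 20).
    shimmer_pct : SD of the cycle-to-cycle amplitude perturbation, % of the
        nominal amplitude (0 <= shimmer < 50).
    open_quotient : open fraction of each glottal cycle, in (0, 1).
    noise_snr_db : aspiration-noise level as a signal-to-noise ratio in dB;
        ``inf`` (or None) means noise-free.
    """

    f0: float = 120.0
    jitter_pct: float = 0.5
    shimmer_pct: float = 2.0
    open_quotient: float = 0.6
    noise_snr_db: float | None = 30.0

    def __post_init__(self) -> None:
        if not (self.f0 > 0):
            raise ValidationError("f0 must be positive")
        if not (0 <= self.jitter_pct < 20):
            raise ValidationError("jitter_pct must be in [0, 20)")
        if not (0 <= self.shimmer_pct < 50):
            raise ValidationError("shimmer_pct must be in [0, 50)")
        if not (0 < self.open_quotient < 1):
            raise ValidationError("open_quotient must be in (0, 1)")
        if self.noise_snr_db is None:
            self.noise_snr_db = math.inf
        if math.isnan(self.noise_snr_db):
            raise ValidationError("noise_snr_db must not be NaN")


@dataclass
class VocalTractParams:
    """Vocal-tract resonances. Defaults are textbook values for /a/."""

    formant_freqs: tuple[float, ...] = (800.0, 1200.0, 2500.0, 3500.0)
    formant_bandwidths: tuple[float, ...] = (80.0, 90.0, 120.0, 130.0)
    drift_amplitude: float = 0.0   # peak sinusoidal modulation of F1 and F2, Hz
    drift_rate: float = 3.0        # modulation frequency, Hz

    def __post_init__(self) -> None:
        f = tuple(float(x) for x in self.formant_freqs)
        b = tuple(float(x) for x in self.formant_bandwidths)
        if len(f) != len(b) or len(f) == 0:
            raise ValidationError("formant freq/bandwidth lists must match and be non-empty")
        if any(f2 <= f1 for f1, f2 in zip(f, f[1:])):
            raise ValidationError("formant_freqs must be strictly increasing")
        if any(x <= 0 for x in b):
            raise ValidationError("bandwidths must be positive")
        if self.drift_amplitude < 0:
            raise ValidationError("drift_amplitude must be >= 0")
        if self.drift_rate <= 0:
            raise ValidationError("drift_rate must be positive")
        self.formant_freqs, self.formant_bandwidths = f, b


@dataclass
class VowelSpec:
    """Full specification of one synthetic sustained-vowel recording."""

    source: GlottalSourceParams = field(default_factory=GlottalSourceParams)
    tract: VocalTractParams = field(default_factory=VocalTractParams)
    duration_s: float = 1.0
    sample_rate_hz: float = 44100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.duration_s > 0):
            raise ValidationError("duration_s must be positive")
        if self.sample_rate_hz < 8000:
            raise ValidationError("sample_rate_hz must be >= 8000")
        if self.duration_s * self.sample_rate_hz > MAX_SAMPLES:
            raise SizeError(
                f"requested {self.duration_s * self.sample_rate_hz:.0f} samples "
                f"exceeds budget {MAX_SAMPLES}")


# --------------------------------------------------------------------------
# glottal source
# --------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, size: int | None = None):
    """Standard normal truncated at +/-3 SD (avoids period collapse)."""
    z = rng.standard_normal(size)
    return np.clip(z, -3.0, 3.0)


def _rosenberg_flow_phase(phase: np.ndarray, open_quotient: float,
                          rise_fraction: float = 2.0 / 3.0) -> np.ndarray:
    """Rosenberg glottal flow as a function of cycle phase in [0, 1).

    Rising cosine ramp over ``rise_fraction`` of the open phase, falling
    quarter-cosine back to zero over the rest, closed (zero flow) for the
    remainder of the cycle. Peak amplitude 1.
    """
    p_rise = rise_fraction * open_quotient
    p_fall = open_quotient - p_rise
    g = np.zeros_like(phase)
    rising = phase < p_rise
    g[rising] = 0.5 * (1.0 - np.cos(np.pi * phase[rising] / p_rise))
    falling = (phase >= p_rise) & (phase < open_quotient)
    g[falling] = np.cos(np.pi * (phase[falling] - p_rise) / (2.0 * p_fall))
    return g


def glottal_pulse_train(source: GlottalSourceParams, duration_s: float,
                        sample_rate_hz: float,
                        rng: np.random.Generator | int | None = None,
                        derivative: bool = True) -> np.ndarray:
    """Generate the (optionally differentiated) glottal pulse train.

    Each cycle is sampled from the continuous pulse shape at its exact
    fractional onset, so an unperturbed train is a sampled periodic signal
    with no cycle-length rounding artifacts. With ``derivative=False`` the
    raw flow is returned, which is convenient for measuring per-cycle peak
    amplitudes directly.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    fs = float(sample_rate_hz)
    n_total = int(round(duration_s * fs))
    if n_total > MAX_SAMPLES:
        raise SizeError("pulse train exceeds sample budget")
    period0 = fs / source.f0
    out = np.zeros(n_total)
    pos = 0.0
    while pos < n_total:
        period = period0 * (1.0 + _truncated_normal(rng) * source.jitter_pct / 100.0)
        period = max(period, 4.0)
        amp = max(1.0 + _truncated_normal(rng) * source.shimmer_pct / 100.0, 0.05)
        n = np.arange(int(math.ceil(pos)), min(int(math.ceil(pos + period)), n_total))
        if n.size:
            out[n] += amp * _rosenberg_flow_phase((n - pos) / period,
                                                  source.open_quotient)
        pos += period
    if derivative:
        out = np.diff(out, prepend=out[:1])
    return out


#: source spectral-tilt low-pass: cutoff (Hz) as a function of open quotient.
#: A longer open phase lowers the maximum flow declination rate, weakening
#: high-frequency excitation; modelled as a one-pole low-pass on the source
#: whose cutoff falls as the open quotient rises (Klatt-style tilt control).
def _tilt_cutoff_hz(open_quotient: float) -> float:
    return 6000.0 * (1.0 - open_quotient) ** 2 + 250.0


def _apply_tilt(x: np.ndarray, open_quotient: float, fs: float) -> np.ndarray:
    a = math.exp(-2.0 * math.pi * _tilt_cutoff_hz(open_quotient) / fs)
    return sps.lfilter([1.0 - a], [1.0, -a], x)


# --------------------------------------------------------------------------
# vocal-tract filter
# --------------------------------------------------------------------------

def _resonator_coeffs(freq: float, bandwidth: float, fs: float):
    """Unity-DC-gain digital resonator (2nd-order all-pole)."""
    r = math.exp(-math.pi * bandwidth / fs)
    theta = 2.0 * math.pi * freq / fs
    a = np.array([1.0, -2.0 * r * math.cos(theta), r * r])
    b = np.array([a.sum()])  # H(z=1) = 1
    return b, a

def _apply_formants(x: np.ndarray, tract: VocalTractParams, fs: float) -> np.ndarray:
    """Cascade resonator filtering; F1/F2 drift handled block-wise."""
    freqs = np.array(tract.formant_freqs)
    bws = np.array(tract.formant_bandwidths)
    if tract.drift_amplitude == 0:
        y = x
        for f, bw in zip(freqs, bws):
            b, a = _resonator_coeffs(f, bw, fs)
            y = sps.lfilter(b, a, y)
        return y

    block = max(32, int(round(0.005 * fs)))  # coefficient update every ~5 ms
    y = np.empty_like(x)
    n = x.size
    zis = [np.zeros(2) for _ in freqs]
    for start in range(0, n, block):
        stop = min(start + block, n)
        t_mid = (start + stop) / 2.0 / fs
        drift = tract.drift_amplitude * math.sin(2.0 * math.pi * tract.drift_rate * t_mid)
        seg = x[start:stop]
        for k, (f, bw) in enumerate(zip(freqs, bws)):
            fk = f + drift if k < 2 else f  # drift on F1/F2 only, same phase
            b, a = _resonator_coeffs(fk, bw, fs)
            seg, zis[k] = sps.lfilter(b, a, seg, zi=zis[k])
        y[start:stop] = seg
    return y


_WARMUP_S = 0.05  # generated and discarded so output is steady state


def synthesize_vowel(spec: VowelSpec) -> Waveform:
    """Synthesize a sustained vowel per ``spec``.

    Returns a mono waveform of the requested duration and rate, DC-free and
    normalized to peak |1|.
    """
    fs = spec.sample_rate_hz
    rng = np.random.default_rng(spec.seed)
    total_s = spec.duration_s + _WARMUP_S
    if total_s * fs > MAX_SAMPLES:
        raise SizeError("requested duration exceeds sample budget")
    source = glottal_pulse_train(spec.source, total_s, fs, rng)
    source = _apply_tilt(source, spec.source.open_quotient, fs)
    y = _apply_formants(source, spec.tract, fs)
    y = y[int(round(_WARMUP_S * fs)):]
    n = int(round(spec.duration_s * fs))
    y = y[:n]
    snr = spec.source.noise_snr_db
    if snr is not None and math.isfinite(snr):
        rms = math.sqrt(float(np.mean(y ** 2)))
        noise_sd = rms * 10.0 ** (-snr / 20.0)
        y = y + noise_sd * rng.standard_normal(y.size)
    y = y - y.mean()
    peak = np.max(np.abs(y))
    if peak > 0:
        y = y / peak
    return Waveform(y, fs)


# --------------------------------------------------------------------------
# synthetic cohorts
# --------------------------------------------------------------------------

@dataclass
class AssessmentDistributions:
    """Distributions for the clinical assessment items.

    Defaults give roughly 15% frailty prevalence on each index, in line
    with population estimates of frailty prevalence in older adults
    (12%-24%); they deliberately do not claim to match any particular
    clinical sample.
    """

    female_prev: float = 0.55
    body_weight_mean_kg: float = 60.0
    body_weight_sd_kg: float = 10.0
    weight_loss_prob: float = 0.50        # probability of any loss in the past year
    weight_loss_mean_kg: float = 5.0      # exponential mean of the loss, given any
    exhaustion_prev: float = 0.50
    chair_rise_unable_prev: float = 0.30
    grip_mean_male_kg: float = 28.5
    grip_sd_male_kg: float = 6.0
    grip_mean_female_kg: float = 19.0
    grip_sd_female_kg: float = 5.0
    gait_mean_mps: float = 1.05
    gait_sd_mps: float = 0.30
    non_ambulatory_prev: float = 0.03
    adl_deterioration_prev: float = 0.30

    def __post_init__(self) -> None:
        for name in ("female_prev", "weight_loss_prob", "exhaustion_prev",
                     "chair_rise_unable_prev", "non_ambulatory_prev",
                     "adl_deterioration_prev"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} must be a probability in [0, 1]")
        for name in ("body_weight_sd_kg", "grip_sd_male_kg", "grip_sd_female_kg",
                     "gait_sd_mps"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class FeatureLinkModel:
    """Mean A1-A4 as a function of true phenotype status (mode ``"phenotype"``).

    mean(A) = base[A] + ebf_frail_shift[A]*1[EBF frail]
                       + sbf_frail_shift[A]*1[SBF frail] + Normal(0, noise_sd[A]).
    Default shifts follow the published directions of association: lower A1
    with energy-based frailty, higher A2/A3 with sarcopenia-based frailty,
    higher A4 with energy-based frailty.
    """

    base: dict = field(default_factory=lambda: {
        "A1": 0.060, "A2": 6.0, "A3": 12.0, "A4": 0.70})
    ebf_frail_shift: dict = field(default_factory=lambda: {
        "A1": -0.012, "A2": 0.0, "A3": 0.0, "A4": 0.08})
    sbf_frail_shift: dict = field(default_factory=lambda: {
        "A1": 0.0, "A2": 3.0, "A3": 6.0, "A4": 0.0})
    noise_sd: dict = field(default_factory=lambda: {
        "A1": 0.008, "A2": 1.5, "A3": 4.0, "A4": 0.05})

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            for d in (self.base, self.ebf_frail_shift, self.sbf_frail_shift,
                      self.noise_sd):
                d.setdefault(name, 0.0)
            if self.noise_sd[name] < 0:
                raise ValidationError("noise_sd must be >= 0")


@dataclass
class OutcomeLink:
    """Logistic feature->outcome link for mode ``"logistic"``.

    P(outcome=1) = expit(intercept + sum over features of coefficients[A]*A);
    coefficients are log-odds per natural unit of the feature.
    """

    intercept: float = -3.15
    coefficients: dict = field(default_factory=lambda: {"A2": math.log(1.34)})
    outcome_name: str = "outcome"


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort."""

    n_subjects: int = 100
    assessment: AssessmentDistributions = field(default_factory=AssessmentDistributions)
    feature_model: FeatureLinkModel = field(default_factory=FeatureLinkModel)
    outcome_link: OutcomeLink | None = None
    mode: str = "phenotype"   # "phenotype" (mode 1) or "logistic" (mode 2)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValidationError("n_subjects must be >= 0")
        if self.mode not in ("phenotype", "logistic"):
            raise ConfigurationError(f"unknown cohort mode {self.mode!r}")
        if self.mode == "logistic" and self.outcome_link is None:
            raise ConfigurationError("mode='logistic' requires an outcome_link")


class CohortTables(NamedTuple):
    assessments: pd.DataFrame
    features: pd.DataFrame
    outcomes: pd.DataFrame


ASSESSMENT_COLUMNS = [
    "subject_id", "sex", "weight_loss_kg", "weight_loss_pct", "exhaustion",
    "chair_rise_unable", "grip_kg", "gait_speed_mps", "non_ambulatory",
    "adl_deterioration",
]


def _draw_assessments(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    d = spec.assessment
    n = spec.n_subjects
    sex = np.where(rng.random(n) < d.female_prev, "female", "male")
    weight = np.maximum(rng.normal(d.body_weight_mean_kg, d.body_weight_sd_kg, n), 30.0)
    any_loss = rng.random(n) < d.weight_loss_prob
    loss_kg = np.where(any_loss, rng.exponential(max(d.weight_loss_mean_kg, 1e-12), n), 0.0)
    loss_kg = np.minimum(loss_kg, 0.3 * weight)  # physical cap on annual loss
    loss_pct = 100.0 * loss_kg / weight
    grip = np.where(
        sex == "male",
        rng.normal(d.grip_mean_male_kg, d.grip_sd_male_kg, n),
        rng.normal(d.grip_mean_female_kg, d.grip_sd_female_kg, n),
    )
    grip = np.maximum(grip, 0.0)
    gait = np.maximum(rng.normal(d.gait_mean_mps, d.gait_sd_mps, n), 0.0)
    non_amb = rng.random(n) < d.non_ambulatory_prev
    gait = np.where(non_amb, np.nan, gait)  # wheelchair users do not walk the 4 m
    return pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "sex": sex,
        "weight_loss_kg": np.round(loss_kg, 3),
        "weight_loss_pct": np.round(loss_pct, 3),
        "exhaustion": rng.random(n) < d.exhaustion_prev,
        "chair_rise_unable": rng.random(n) < d.chair_rise_unable_prev,
        "grip_kg": np.round(grip, 2),
        "gait_speed_mps": np.round(gait, 3),
        "non_ambulatory": non_amb,
        "adl_deterioration": rng.random(n) < d.adl_deterioration_prev,
    })


def _score_assessments(assess: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, row in assess.iterrows():
        res = score_record(AssessmentRecord.from_row(row))
        rows.append(res.to_dict())
    if not rows:
        from .phenotypes import PHENOTYPE_COLUMNS
        return pd.DataFrame(columns=PHENOTYPE_COLUMNS)
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec) -> CohortTables:
    """Generate a synthetic cohort per ``spec`` (see module docstring)."""
    rng = np.random.default_rng(spec.seed)
    assess = _draw_assessments(spec, rng)
    n = spec.n_subjects
    fm = spec.feature_model

    if spec.mode == "phenotype":
        pheno = _score_assessments(assess)
        ebf_frail = (pheno["ebf_status"] == "frail").to_numpy() if n else np.zeros(0, bool)
        sbf_frail = (pheno["sbf_status"] == "frail").to_numpy() if n else np.zeros(0, bool)
        feat = {"subject_id": assess["subject_id"]}
        for name in FEATURE_NAMES:
            mu = (fm.base[name]
                  + fm.ebf_frail_shift[name] * ebf_frail
                  + fm.sbf_frail_shift[name] * sbf_frail)
            feat[name] = mu + fm.noise_sd[name] * rng.standard_normal(n)
        features = pd.DataFrame(feat)
        return CohortTables(assess, features, pheno)

    # mode "logistic": marginal features, then Bernoulli outcome via the link
    link = spec.outcome_link
    assert link is not None  # enforced by CohortSpec
    feat = {"subject_id": assess["subject_id"]}
    for name in FEATURE_NAMES:
        feat[name] = fm.base[name] + fm.noise_sd[name] * rng.standard_normal(n)
    features = pd.DataFrame(feat)
    eta = np.full(n, float(link.intercept))
    for name, coef in link.coefficients.items():
        if name not in FEATURE_NAMES:
            raise ConfigurationError(f"outcome_link references unknown feature {name!r}")
        eta = eta + coef * features[name].to_numpy()
    p = 1.0 / (1.0 + np.exp(-eta))
    outcome = (rng.random(n) < p).astype(int)
    outcomes = pd.DataFrame({
        "subject_id": assess["subject_id"],
        link.outcome_name: outcome,
    })
    return CohortTables(assess, features, outcomes)
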