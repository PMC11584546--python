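"""Pipeline configuration: one YAML-serializable object for every stage.

All study thresholds (15% repeat variability, 0.8/1.2 s duration gate,
800 Hz end frequency, 4.5 kg / 5% weight loss, 28/18 kg grip cutoffs,
1.0 m/s gait cutoff) live here as defaults rather than being hard-coded in
the stages.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .features import A2Config, A3Config, A4Config, FrameConfig
from .phenotypes import ScoringThresholds
from .preprocess import EndpointConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # paths
    audio_dir: str = "audio"
    assessment_csv: str = "assessments.csv"
    output_dir: str = "out"
    # preprocess
    endpoint: EndpointConfig = field(default_factory=EndpointConfig)
    duration_min_s: float = 0.8
    duration_max_s: float = 1.2
    variability_threshold_pct: float = 15.0
    # features
    frame: FrameConfig = field(default_factory=FrameConfig)
    a2_relative: bool = True
    a3: A3Config = field(default_factory=A3Config)
    end_frequency_hz: float = 800.0
    sample_rate_hz: float = 44100.0
    # phenotypes
    thresholds: ScoringThresholds = field(default_factory=ScoringThresholds)
    # models
    outcomes: tuple[str, ...] = ("EBF-frail", "SBF-frail", "HBF-E", "HBF-S",
                                 "four_category")
    exposures: tuple[str, ...] = ("A1", "A2", "A3", "A4")
    standardize_exposure: bool = False
    covariates: tuple[str, ...] = ()
    # synthesis / reproducibility
    n_subjects: int = 60
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.duration_min_s < self.duration_max_s):
            raise ConfigurationError("need 0 < duration_min_s < duration_max_s")
        if self.variability_threshold_pct <= 0:
            raise ConfigurationError("variability_threshold_pct must be > 0")
        if not (0 < self.end_frequency_hz < self.sample_rate_hz / 2.0):
            raise ConfigurationError("end_frequency_hz must be below Nyquist")

    def a2_config(self) -> A2Config:
        return A2Config(frame_length_s=self.frame.frame_length_s,
                        hop_length_s=self.frame.hop_length_s,
                        window=self.frame.window, relative=self.a2_relative)

    def a4_config(self) -> A4Config:
        return A4Config(end_frequency_hz=self.end_frequency_hz)

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (("endpoint", EndpointConfig), ("frame", FrameConfig),
                         ("a3", A3Config), ("thresholds", ScoringThresholds)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        for key in ("outcomes", "exposures", "covariates"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
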