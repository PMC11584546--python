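"""Rule-based frailty phenotype scoring.

Two frailty indices are scored from clinical assessment items:

* **EBF** (energy-based frailty), 2 criteria — unintentional weight loss
  (>= 4.5 kg or > 5% of body weight in the previous year) and exhaustion.
  2 criteria met -> frail, 1 -> prefrail, 0 -> robust.
* **SBF** (sarcopenia-based frailty), 4 criteria — inability to rise from a
  chair 5 consecutive times without using the arms; low grip strength
  (< 28 kg for men, < 18 kg for women, dominant hand, Asian cutoffs); low
  walking ability (gait speed < 1.0 m/s, or inability to perform the walk,
  e.g. wheelchair users); low physical activity (deterioration in basic
  activities of daily living). >= 3 criteria -> frail, 1-2 -> prefrail,
  0 -> robust.

Two hybrid phenotypes combine the indices: **HBF-E** is EBF-frail while at
least prefrail on SBF; **HBF-S** is SBF-frail while at least prefrail on
EBF. A 4-category outcome (nonfrail / EBF-only / SBF-only / both) uses the
frail statuses of the two indices.

Boundary conventions (recorded, configurable via :class:`ScoringThresholds`):
"at least 4.5 kg" is inclusive; "> 5%" strict; gait "< 1.0 m/s" strict; grip
cutoffs strict (low grip iff grip < cutoff). Missing required items make a
status *indeterminate*; subjects with indeterminate statuses are excluded
from models that use that outcome (complete-case).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ScoringThresholds",
    "AssessmentRecord",
    "PhenotypeResult",
    "score_ebf",
    "score_sbf",
    "derive_hybrids",
    "score_record",
    "score_table",
    "INDETERMINATE",
    "FOUR_CATEGORIES",
    "PHENOTYPE_COLUMNS",
]

INDETERMINATE = "indeterminate"
STATUSES = ("robust", "prefrail", "frail")
FOUR_CATEGORIES = ("nonfrail", "EBF-only", "SBF-only", "both")

PHENOTYPE_COLUMNS = [
    "subject_id", "ebf_criteria_met", "ebf_status", "sbf_criteria_met",
    "sbf_status", "hbf_e", "hbf_s", "four_category",
]


@dataclass(frozen=True)
class ScoringThresholds:
    """Cutoffs for the phenotype criteria (defaults as published)."""

    weight_loss_kg: float = 4.5        # inclusive: loss >= 4.5 kg
    weight_loss_pct: float = 5.0       # strict: loss > 5%
    grip_cutoff_male_kg: float = 28.0  # strict: grip < cutoff
    grip_cutoff_female_kg: float = 18.0
    gait_cutoff_mps: float = 1.0       # strict: gait < 1.0 m/s


def _missing(x: Any) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and np.isnan(x):
        return True
    return x is pd.NA or x is pd.NaT


def _as_bool(x: Any) -> bool | None:
    """Coerce yes/no style values; None for missing."""
    if _missing(x):
        return None
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, str):
        s = x.strip().lower()
        if s in ("yes", "y", "true", "1"):
            return True
        if s in ("no", "n", "false", "0"):
            return False
        raise ValueError(f"cannot interpret {x!r} as yes/no")
    return bool(int(x))


@dataclass
class AssessmentRecord:
    """Per-subject clinical items feeding phenotype scoring.

    Numeric fields may be missing (None/NaN). ``weight_loss_flag`` may be
    supplied directly instead of the raw kg/% fields.
    """

    subject_id: str = ""
    sex: str | None = None                 # "male" / "female"
    weight_loss_kg: float | None = None
    weight_loss_pct: float | None = None
    weight_loss_flag: bool | None = None   # optional precomputed criterion
    exhaustion: bool | None = None
    chair_rise_unable: bool | None = None
    grip_kg: float | None = None
    gait_speed_mps: float | None = None
    non_ambulatory: bool | None = None
    adl_deterioration: bool | None = None

    def __post_init__(self) -> None:
        for name in ("weight_loss_kg", "grip_kg", "gait_speed_mps"):
            v = getattr(self, name)
            if not _missing(v) and v < 0:
                raise ValueError(f"{name} must be >= 0 when present")
        if not _missing(self.weight_loss_pct) and not (0 <= self.weight_loss_pct <= 100):
            raise ValueError("weight_loss_pct must be in [0, 100] when present")
        if self.sex is not None:
            s = str(self.sex).strip().lower()
            if s not in ("male", "female"):
                raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
            self.sex = s
        for name in ("weight_loss_flag", "exhaustion", "chair_rise_unable",
                     "non_ambulatory", "adl_deterioration"):
            setattr(self, name, _as_bool(getattr(self, name)))

    @classmethod
    def from_row(cls, row: Mapping[str, Any]) -> "AssessmentRecord":
        """Build a record from a table row (extra columns ignored)."""
        kwargs = {}
        for name in cls.__dataclass_fields__:
            if name in row and not _missing(row[name]):
                kwargs[name] = row[name]
        return cls(**kwargs)


@dataclass
class PhenotypeResult:
    """Scored statuses for one subject."""

    subject_id: str
    ebf_criteria_met: int | None
    ebf_status: str
    sbf_criteria_met: int | None
    sbf_status: str
    hbf_e: bool | None
    hbf_s: bool | None
    four_category: str

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in PHENOTYPE_COLUMNS}


def _count_to_status(count: int, frail_at: int) -> str:
    if count >= frail_at:
        return "frail"
    return "prefrail" if count >= 1 else "robust"


def score_ebf(r: AssessmentRecord,
              thresholds: ScoringThresholds = ScoringThresholds()
              ) -> tuple[int | None, str]:
    """Score the 2-criterion energy-based frailty index.

    Returns ``(criteria_met, status)``; status is ``"indeterminate"`` (with
    ``criteria_met`` None) when a required item is missing.
    """
    t = thresholds
    if r.weight_loss_flag is not None:
        wl = r.weight_loss_flag
    else:
        kg, pct = r.weight_loss_kg, r.weight_loss_pct
        if _missing(kg) and _missing(pct):
            return None, INDETERMINATE
        wl = ((not _missing(kg) and kg >= t.weight_loss_kg)
              or (not _missing(pct) and pct > t.weight_loss_pct))
    if r.exhaustion is None:
        return None, INDETERMINATE
    met = int(wl) + int(r.exhaustion)
    return met, _count_to_status(met, frail_at=2)


def score_sbf(r: AssessmentRecord,
              thresholds: ScoringThresholds = ScoringThresholds()
              ) -> tuple[int | None, str]:
    """Score the 4-criterion sarcopenia-based frailty index.

    Low walking ability is met by slow gait OR inability to walk (e.g. a
    wheelchair user); a missing gait speed therefore does not make the
    status indeterminate when ``non_ambulatory`` is true.
    """
    t = thresholds
    if r.chair_rise_unable is None:
        return None, INDETERMINATE
    c1 = r.chair_rise_unable

    if _missing(r.grip_kg) or r.sex is None:
        return None, INDETERMINATE
    cutoff = t.grip_cutoff_male_kg if r.sex == "male" else t.grip_cutoff_female_kg
    c2 = r.grip_kg < cutoff

    if r.non_ambulatory:
        c3 = True
    elif not _missing(r.gait_speed_mps):
        c3 = r.gait_speed_mps < t.gait_cutoff_mps
    else:
        return None, INDETERMINATE

    if r.adl_deterioration is None:
        return None, INDETERMINATE
    c4 = r.adl_deterioration

    met = int(c1) + int(c2) + int(c3) + int(c4)
    return met, _count_to_status(met, frail_at=3)


def derive_hybrids(ebf_status: str, sbf_status: str
                   ) -> tuple[bool | None, bool | None, str]:
    """Derive HBF-E, HBF-S and the 4-category label from the two statuses."""
    if ebf_status == INDETERMINATE or sbf_status == INDETERMINATE:
        return None, None, INDETERMINATE
    if ebf_status not in STATUSES or sbf_status not in STATUSES:
        raise ValueError(f"unknown status {(ebf_status, sbf_status)!r}")
    hbf_e = ebf_status == "frail" and sbf_status in ("prefrail", "frail")
    hbf_s = sbf_status == "frail" and ebf_status in ("prefrail", "frail")
    if ebf_status == "frail" and sbf_status == "frail":
        four = "both"
    elif ebf_status == "frail":
        four = "EBF-only"
    elif sbf_status == "frail":
        four = "SBF-only"
    else:
        four = "nonfrail"
    return hbf_e, hbf_s, four


def score_record(r: AssessmentRecord,
                 thresholds: ScoringThresholds = ScoringThresholds()
                 ) -> PhenotypeResult:
    """Score one subject: both indices, hybrid flags, 4-category label."""
    ebf_met, ebf_status = score_ebf(r, thresholds)
    sbf_met, sbf_status = score_sbf(r, thresholds)
    hbf_e, hbf_s, four = derive_hybrids(ebf_status, sbf_status)
    return PhenotypeResult(r.subject_id, ebf_met, ebf_status, sbf_met,
                           sbf_status, hbf_e, hbf_s, four)


def score_table(assessments: pd.DataFrame,
                thresholds: ScoringThresholds = ScoringThresholds()
                ) -> pd.DataFrame:
    """Score every row of an assessment table; returns the phenotype table."""
    rows = [score_record(AssessmentRecord.from_row(row), thresholds).to_dict()
            for _, row in assessments.iterrows()]
    if not rows:
        return pd.DataFrame(columns=PHENOTYPE_COLUMNS)
    return pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)
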