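"""End-to-end orchestration: synthesize a study, or run the analysis stages.

``run_synth`` writes a complete synthetic study to disk: three sustained-
vowel WAV recordings per subject (with leading/trailing room noise so the
endpoint detector has real work), the assessment table, the model-generated
feature table, the outcome (phenotype) table, and a truth manifest with the
generating parameters. ``run_pipeline`` consumes a directory of recordings
plus an assessment CSV and produces the per-subject QC report, accepted
feature table, phenotype table, association results, and a run manifest.
Both are deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (MULTINOMIAL_OUTCOME, FrailtyAssociationModel,
                          ModelSpec, fit_binomial, fit_multinomial)
from .config import PipelineConfig
from .exceptions import (InsufficientDataError, SeparationError,
                         VoxfrailError, ZeroVarianceError)
from .features import compute_a1, compute_a2, compute_a3, compute_a4
from .phenotypes import score_table
from .preprocess import (PARAMETER_NAMES, QCReport, RecordingQC,
                         detect_endpoints, select_repeats, validate_duration)
from .synth import (CohortSpec, GlottalSourceParams, VocalTractParams,
                    VowelSpec, generate_cohort, synthesize_vowel)
from .waveform import Waveform, read_wav, write_wav

__all__ = ["run_synth", "run_pipeline", "PipelineResult"]

logger = logging.getLogger(__name__)

N_REPEATS = 3


# --------------------------------------------------------------------------
# synthetic study on disk
# --------------------------------------------------------------------------

def _subject_vowel_params(sex: str, ebf_frail: bool, sbf_frail: bool,
                          rng: np.random.Generator
                          ) -> tuple[GlottalSourceParams, VocalTractParams]:
    """Phenotype-linked synthesis knobs for one subject.

    Directions follow the published associations: energy-based frailty
    lowers A1 (more aspiration noise lowers? no — less noise) — concretely,
    EBF shifts the source toward breathier phonation (higher open quotient,
    lower SNR raises A1; EBF subjects get *higher* SNR so their A1 is
    lower) and sarcopenia-based frailty destabilizes amplitude and formants
    (more shimmer and formant drift, raising A2 and A3).
    """
    f0 = rng.normal(200.0 if sex == "female" else 115.0, 8.0)
    shimmer = max(1.0 + 3.5 * sbf_frail + rng.normal(0, 0.3), 0.0)
    jitter = max(0.4 + rng.normal(0, 0.05), 0.0)
    oq = float(np.clip(0.55 + 0.15 * ebf_frail + rng.normal(0, 0.02), 0.2, 0.9))
    snr = 28.0 + 8.0 * ebf_frail + rng.normal(0, 1.0)
    drift = max(8.0 + 20.0 * sbf_frail + rng.normal(0, 1.5), 0.0)
    source = GlottalSourceParams(f0=f0, jitter_pct=jitter, shimmer_pct=shimmer,
                                 open_quotient=oq, noise_snr_db=snr)
    tract = VocalTractParams(drift_amplitude=drift)
    return source, tract


def _pad_with_room_noise(w: Waveform, pad_s: float, fs: float,
                         rng: np.random.Generator) -> Waveform:
    """Surround a vowel with low-level noise 'silence' (about -55 dB)."""
    n_pad = int(round(pad_s * fs))
    noise = lambda n: 10 ** (-55 / 20) * rng.standard_normal(n)
    samples = np.concatenate([noise(n_pad), w.samples, noise(n_pad)])
    peak = np.max(np.abs(samples))
    return Waveform(samples / peak, fs, subject_id=w.subject_id,
                    repeat_index=w.repeat_index)


def run_synth(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Write a synthetic study (WAVs + tables + truth manifest) to disk."""
    cfg.validate()
    out = Path(out_dir if out_dir is not None else cfg.output_dir)
    audio_dir = out / "audio"
    audio_dir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(cfg.seed)
    cohort_seed, audio_seed = (int(s) % (2 ** 31) for s in ss.generate_state(2))
    cohort = generate_cohort(CohortSpec(n_subjects=cfg.n_subjects,
                                        mode="phenotype", seed=cohort_seed))
    if cfg.n_subjects == 0:
        logger.warning("n_subjects = 0: writing empty tables with headers")

    rng = np.random.default_rng(audio_seed)
    truth: dict[str, dict] = {}
    fs = cfg.sample_rate_hz
    for i, row in cohort.assessments.iterrows():
        sid = row["subject_id"]
        pheno = cohort.outcomes.iloc[i]
        ebf_frail = pheno["ebf_status"] == "frail"
        sbf_frail = pheno["sbf_status"] == "frail"
        source, tract = _subject_vowel_params(row["sex"], ebf_frail,
                                              sbf_frail, rng)
        truth[sid] = {
            "f0": source.f0, "shimmer_pct": source.shimmer_pct,
            "jitter_pct": source.jitter_pct,
            "open_quotient": source.open_quotient,
            "noise_snr_db": source.noise_snr_db,
            "drift_amplitude": tract.drift_amplitude,
            "ebf_status": pheno["ebf_status"], "sbf_status": pheno["sbf_status"],
        }
        for rep in range(1, N_REPEATS + 1):
            dur = float(np.clip(rng.normal(1.0, 0.07), 0.75, 1.25))
            spec = VowelSpec(source=source, tract=tract, duration_s=dur,
                             sample_rate_hz=fs,
                             seed=int(rng.integers(2 ** 31)))
            vowel = synthesize_vowel(spec)
            vowel.subject_id, vowel.repeat_index = sid, rep
            padded = _pad_with_room_noise(vowel, pad_s=0.2, fs=fs, rng=rng)
            write_wav(audio_dir / f"{sid}_rep{rep}.wav", padded)

    cohort.assessments.to_csv(out / "assessments.csv", index=False)
    cohort.features.to_csv(out / "features_generated.csv", index=False)
    cohort.outcomes.to_csv(out / "outcomes.csv", index=False)
    with open(out / "truth_manifest.json", "w") as fh:
        json.dump({"seed": cfg.seed, "n_subjects": cfg.n_subjects,
                   "subjects": truth}, fh, indent=1, sort_keys=True)
    return {"audio_dir": str(audio_dir),
            "assessment_csv": str(out / "assessments.csv"),
            "n_wav": cfg.n_subjects * N_REPEATS}


# --------------------------------------------------------------------------
# analysis pipeline
# --------------------------------------------------------------------------

@dataclass
class PipelineResult:
    qc: pd.DataFrame
    features: pd.DataFrame
    phenotypes: pd.DataFrame
    analysis_table: pd.DataFrame
    associations: pd.DataFrame
    manifest: dict
    output_dir: Path | None = None
    errors: list[str] = field(default_factory=list)


def _qc_row(subject_id: str, recordings: list[RecordingQC],
            report: QCReport | None, reason: str = "") -> dict:
    row: dict = {"subject_id": subject_id}
    for i in range(N_REPEATS):
        rec = recordings[i] if i < len(recordings) else None
        row[f"rep{i + 1}_duration_s"] = rec.trimmed_duration_s if rec else np.nan
        row[f"rep{i + 1}_duration_pass"] = rec.duration_pass if rec else False
    for name in PARAMETER_NAMES:
        row[f"{name}_cv_pct"] = (report.per_parameter_cv_pct.get(name, np.nan)
                                 if report else np.nan)
        row[f"{name}_pass"] = (report.variability_pass.get(name, False)
                               if report else False)
        row[f"{name}_accepted"] = (report.accepted_values.get(name, np.nan)
                                   if report else np.nan)
    reasons = list(report.reasons) if report else []
    if reason:
        reasons.insert(0, reason)
    row["reason"] = ";".join(reasons)
    return row


def _extract_all(w: Waveform, cfg: PipelineConfig) -> dict[str, float]:
    return {
        "A1": compute_a1(w, cfg.frame),
        "A2": compute_a2(w, cfg.a2_config()),
        "A3": compute_a3(w, cfg.a3),
        "A4": compute_a4(w, cfg.a4_config()),
    }


def qc_subject(waveforms: list[Waveform], cfg: PipelineConfig
               ) -> tuple[list[RecordingQC], QCReport | None, str]:
    """Trim, duration-gate and variability-check one subject's repeats.

    Returns (per-recording QC, repeat-selection report or None, reason).
    """
    recqc: list[RecordingQC] = []
    feats = []
    for w in waveforms:
        trimmed = detect_endpoints(w, cfg.endpoint)
        ok = validate_duration(trimmed, cfg.duration_min_s, cfg.duration_max_s)
        recqc.append(RecordingQC(w.repeat_index, trimmed.duration_s, ok,
                                 "" if ok else "duration"))
        if ok:
            feats.append(_extract_all(trimmed, cfg))
    if len(waveforms) < N_REPEATS:
        return recqc, None, "missing_repeats"
    if len(feats) < N_REPEATS:
        return recqc, None, "duration_gate"
    report = select_repeats(feats, cfg.variability_threshold_pct)
    return recqc, report, ""


def _fit_all_models(analysis: pd.DataFrame, cfg: PipelineConfig
                    ) -> tuple[pd.DataFrame, list[str]]:
    rows, errors = [], []
    n_models = 0
    for outcome in cfg.outcomes:
        for exposure in cfg.exposures:
            spec = ModelSpec(outcome=outcome, exposure=exposure,
                             covariates=cfg.covariates,
                             standardize_exposure=cfg.standardize_exposure)
            n_models += 1
            try:
                if outcome == MULTINOMIAL_OUTCOME:
                    effects = fit_multinomial(spec, analysis)
                else:
                    effects = [fit_binomial(spec, analysis)]
                rows.extend(e.to_dict() | {"status": "ok"} for e in effects)
            except (VoxfrailError, ValueError) as exc:
                errors.append(f"{outcome} ~ {exposure}: {exc}")
                rows.append({"outcome": outcome, "exposure": exposure,
                             "effect_type": None, "category": None,
                             "baseline_category": None, "estimate": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan,
                             "se_log": np.nan, "p_value": np.nan,
                             "n_used": 0,
                             "status": f"error:{type(exc).__name__}"})
    results = pd.DataFrame(rows)
    results["n_models_fitted"] = n_models  # multiple-testing disclosure
    return results, errors


def run_pipeline(cfg: PipelineConfig, write: bool = True) -> PipelineResult:
    """Run QC -> features -> phenotypes -> association models end to end."""
    cfg.validate()
    audio_dir = Path(cfg.audio_dir)
    assessments = pd.read_csv(cfg.assessment_csv)
    _validate_assessment_schema(assessments)
    phenotypes = score_table(assessments, cfg.thresholds)

    qc_rows, feat_rows = [], []
    errors: list[str] = []
    for sid in assessments["subject_id"]:
        paths = sorted(audio_dir.glob(f"{sid}_rep*.wav"))
        waveforms, read_fail = [], False
        for i, p in enumerate(paths[:N_REPEATS], start=1):
            try:
                waveforms.append(read_wav(p, subject_id=sid, repeat_index=i))
            except Exception as exc:  # corrupt file: flag, keep going
                errors.append(f"{sid}: unreadable recording {p.name}: {exc}")
                read_fail = True
        if read_fail or len(waveforms) < N_REPEATS:
            reason = "read_error" if read_fail else "missing_repeats"
            qc_rows.append(_qc_row(sid, [], None, reason))
            continue
        try:
            recqc, report, reason = qc_subject(waveforms, cfg)
        except VoxfrailError as exc:
            errors.append(f"{sid}: QC failed: {exc}")
            qc_rows.append(_qc_row(sid, [], None, f"qc_error:{type(exc).__name__}"))
            continue
        qc_rows.append(_qc_row(sid, recqc, report, reason))
        if report is not None:
            feat_rows.append({"subject_id": sid, **report.accepted_values})

    qc = pd.DataFrame(qc_rows)
    features = pd.DataFrame(feat_rows,
                            columns=["subject_id", *PARAMETER_NAMES])
    if features.empty or features[list(PARAMETER_NAMES)].isna().all().all():
        raise InsufficientDataError("no subject survived QC: empty analysis")

    analysis = features.merge(phenotypes, on="subject_id", how="inner")
    associations, model_errors = _fit_all_models(analysis, cfg)
    errors.extend(model_errors)

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "n_subjects_assessed": int(len(assessments)),
        "n_subjects_with_accepted_features": int(len(features)),
        "n_models_attempted": int(len(cfg.outcomes) * len(cfg.exposures)),
        "n_model_errors": len(model_errors),
        "errors": errors,
    }
    result = PipelineResult(qc, features, phenotypes, analysis, associations,
                            manifest, errors=errors)
    if write:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        qc.to_csv(out / "qc_report.csv", index=False)
        features.to_csv(out / "features.csv", index=False)
        phenotypes.to_csv(out / "phenotypes.csv", index=False)
        analysis.to_csv(out / "analysis_table.csv", index=False)
        associations.to_csv(out / "associations.csv", index=False)
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        result.output_dir = out
    return result


REQUIRED_ASSESSMENT_COLUMNS = (
    "subject_id", "sex", "exhaustion", "chair_rise_unable",
    "grip_kg", "gait_speed_mps", "non_ambulatory", "adl_deterioration",
)


def _validate_assessment_schema(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_ASSESSMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"assessment CSV missing column(s): {missing}")
    if not ({"weight_loss_kg", "weight_loss_pct", "weight_loss_flag"}
            & set(df.columns)):
        raise ValueError("assessment CSV needs a weight-loss column "
                         "(weight_loss_kg, weight_loss_pct or weight_loss_flag)")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id in assessment CSV: {dup!r}")
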