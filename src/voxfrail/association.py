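"""Per-feature logistic association models.

Each acoustic parameter is evaluated separately against a frailty outcome:

* binary outcomes (EBF-frail, SBF-frail, HBF-E, HBF-S) via binomial
  logistic regression, reporting the odds ratio (OR) per exposure unit with
  a Wald 95% CI;
* the 4-category outcome (nonfrail / EBF-only / SBF-only / both) via
  multinomial logistic regression with *nonfrail* as baseline, reporting a
  relative risk ratio (RRR) per non-baseline category.

The public surface follows the Model/Results idiom:
``FrailtyAssociationModel.from_dataframe(...).fit()`` returns an
:class:`AssociationResults` carrying estimates, their uncertainties,
diagnostics, a ``summary()`` table and a forest-plot method. Maximum
likelihood is computed by Newton iterations with tight tolerances (the
score is ~0 at convergence); perfect or quasi-perfect separation is
detected and raised rather than reported as an implausible estimate.
Subjects with an indeterminate outcome or a missing exposure are excluded
complete-case, with a logged count.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                             PerfectSeparationWarning)

from .exceptions import (ConfigurationError, NonConvergenceError,
                         SeparationError, ZeroVarianceError)
from .phenotypes import FOUR_CATEGORIES, INDETERMINATE

__all__ = [
    "ModelSpec",
    "AssociationResult",
    "AssociationResults",
    "FrailtyAssociationModel",
    "fit_binomial",
    "fit_multinomial",
    "odds_to_probability",
    "BINARY_OUTCOMES",
    "MULTINOMIAL_OUTCOME",
]

logger = logging.getLogger(__name__)

WALD_Z = 1.96  # 95% CI half-width in SEs on the log scale

EXPOSURES = ("A1", "A2", "A3", "A4")

#: binary outcomes -> column/derivation in the merged analysis table
BINARY_OUTCOMES = ("EBF-frail", "SBF-frail", "HBF-E", "HBF-S")
MULTINOMIAL_OUTCOME = "four_category"

_SEPARATION_BETA = 30.0  # |log-OR| beyond this is treated as divergence


@dataclass(frozen=True)
class ModelSpec:
    """One model: a single acoustic exposure against one outcome."""

    outcome: str
    exposure: str
    covariates: tuple[str, ...] = ()
    standardize_exposure: bool = False

    def __post_init__(self) -> None:
        if self.exposure in self.covariates:
            raise ConfigurationError("exposure cannot also be a covariate")


@dataclass
class AssociationResult:
    """One fitted effect: an OR (binomial) or RRR (one multinomial contrast)."""

    effect_type: str            # "OR" or "RRR"
    estimate: float             # exponentiated coefficient, per exposure unit
    ci_low: float
    ci_high: float
    se_log: float
    p_value: float
    n_used: int
    outcome: str
    exposure: str
    category: str | None = None          # multinomial contrast category
    baseline_category: str | None = None

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome, "exposure": self.exposure,
            "effect_type": self.effect_type, "category": self.category,
            "baseline_category": self.baseline_category,
            "estimate": self.estimate, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "se_log": self.se_log,
            "p_value": self.p_value, "n_used": self.n_used,
        }


def odds_to_probability(odds):
    """Convert odds to a probability: p = odds / (1 + odds).

    Accepts scalars or arrays; odds must be >= 0.
    """
    arr = np.asarray(odds, dtype=float)
    if np.any(arr < 0):
        raise ValueError("odds must be non-negative")
    out = arr / (1.0 + arr)
    return float(out) if np.isscalar(odds) or arr.ndim == 0 else out


def _binary_outcome_vector(data: pd.DataFrame, outcome: str) -> pd.Series:
    """Binary outcome as 0/1 with NaN for indeterminate subjects."""
    def from_flag(col: str) -> pd.Series:
        s = data[col]
        out = pd.Series(np.nan, index=data.index, dtype=float)
        out[s == True] = 1.0   # noqa: E712  (may hold None for indeterminate)
        out[s == False] = 0.0  # noqa: E712
        return out

    if outcome in data.columns:
        return from_flag(outcome)
    if outcome == "EBF-frail":
        s = data["ebf_status"]
    elif outcome == "SBF-frail":
        s = data["sbf_status"]
    elif outcome == "HBF-E":
        return from_flag("hbf_e")
    elif outcome == "HBF-S":
        return from_flag("hbf_s")
    else:
        raise ConfigurationError(f"unknown binary outcome {outcome!r}")
    out = pd.Series(np.nan, index=data.index, dtype=float)
    out[s == "frail"] = 1.0
    out[s.isin(["robust", "prefrail"])] = 0.0
    return out


class FrailtyAssociationModel:
    """Univariable (optionally covariate-adjusted) logistic association model.

    Build from a merged analysis table (acoustic features + phenotype
    statuses, one row per subject) with :meth:`from_dataframe`; ``fit()``
    returns an :class:`AssociationResults`.
    """

    def __init__(self, endog: np.ndarray, exog: np.ndarray, *,
                 kind: str, outcome: str, exposure: str,
                 exog_names: Sequence[str],
                 categories: Sequence[str] | None = None,
                 baseline: str | None = None,
                 exposure_scale: float = 1.0):
        self.endog = np.asarray(endog)
        self.exog = np.asarray(exog, dtype=float)
        self.kind = kind
        self.outcome = outcome
        self.exposure = exposure
        self.exog_names = list(exog_names)
        self.categories = list(categories) if categories is not None else None
        self.baseline = baseline
        self.exposure_scale = exposure_scale
        self.n_used = self.exog.shape[0]

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, exposure: str,
                       covariates: Sequence[str] = (),
                       standardize_exposure: bool = False,
                       baseline: str = "nonfrail") -> "FrailtyAssociationModel":
        """Build the model from a merged analysis table.

        ``outcome`` is one of the binary outcomes ("EBF-frail", "SBF-frail",
        "HBF-E", "HBF-S", or any 0/1 column present in ``data``) or
        ``"four_category"`` for the multinomial model with the given
        baseline. ``standardize_exposure`` rescales the exposure to zero
        mean / unit SD, so the reported effect is per SD.
        """
        if exposure not in data.columns:
            raise ConfigurationError(f"exposure column {exposure!r} not in table")
        multinomial = outcome == MULTINOMIAL_OUTCOME
        if multinomial:
            y_raw = data[MULTINOMIAL_OUTCOME]
            valid = y_raw.notna() & (y_raw != INDETERMINATE)
        else:
            y_num = _binary_outcome_vector(data, outcome)
            valid = y_num.notna()
        x = pd.to_numeric(data[exposure], errors="coerce")
        valid &= x.notna()
        for cov in covariates:
            valid &= pd.to_numeric(data[cov], errors="coerce").notna()
        n_excluded = int((~valid).sum())
        if n_excluded:
            logger.info("%s ~ %s: excluded %d subject(s) with indeterminate "
                        "outcome or missing exposure", outcome, exposure, n_excluded)
        sub = data.loc[valid]
        xv = pd.to_numeric(sub[exposure], errors="coerce").to_numpy(float)
        if xv.size == 0 or np.ptp(xv) == 0:
            raise ZeroVarianceError(f"exposure {exposure!r} has zero variance")
        scale = 1.0
        if standardize_exposure:
            sd = xv.std(ddof=0)
            xv = (xv - xv.mean()) / sd
            scale = sd
        cols = [np.ones(xv.size), xv]
        names = ["const", exposure]
        for cov in covariates:
            cols.append(pd.to_numeric(sub[cov], errors="coerce").to_numpy(float))
            names.append(cov)
        exog = np.column_stack(cols)

        if multinomial:
            cats_present = [c for c in FOUR_CATEGORIES
                            if c in set(sub[MULTINOMIAL_OUTCOME])]
            for c in FOUR_CATEGORIES:
                if c not in cats_present:
                    warnings.warn(f"four-category outcome: category {c!r} has "
                                  "zero members and is dropped", stacklevel=2)
            if baseline not in cats_present:
                raise ConfigurationError(
                    f"baseline category {baseline!r} absent from the data")
            if len(cats_present) < 2:
                raise ConfigurationError("multinomial outcome needs >= 2 categories")
            order = [baseline] + [c for c in cats_present if c != baseline]
            codes = sub[MULTINOMIAL_OUTCOME].map({c: i for i, c in enumerate(order)})
            return cls(codes.to_numpy(int), exog, kind="multinomial",
                       outcome=outcome, exposure=exposure, exog_names=names,
                       categories=order, baseline=baseline, exposure_scale=scale)

        yv = _binary_outcome_vector(sub, outcome).to_numpy(float)
        if len(np.unique(yv)) < 2:
            raise ZeroVarianceError(
                f"outcome {outcome!r} has a single level after exclusions")
        return cls(yv, exog, kind="binomial", outcome=outcome,
                   exposure=exposure, exog_names=names, exposure_scale=scale)

    @classmethod
    def from_spec(cls, spec: ModelSpec, data: pd.DataFrame
                  ) -> "FrailtyAssociationModel":
        return cls.from_dataframe(data, spec.outcome, spec.exposure,
                                  covariates=spec.covariates,
                                  standardize_exposure=spec.standardize_exposure)

    # -- estimation --------------------------------------------------------

    def fit(self, maxiter: int = 100, tol: float = 1e-10) -> "AssociationResults":
        """Maximum-likelihood fit (Newton); returns an AssociationResults."""
        if self.kind == "binomial":
            model = sm.Logit(self.endog, self.exog)
        else:
            model = sm.MNLogit(self.endog, self.exog)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=RuntimeWarning)
                warnings.simplefilter("error", category=PerfectSeparationWarning)
                warnings.simplefilter("ignore", category=FutureWarning)
                res = model.fit(method="newton", maxiter=maxiter, tol=tol,
                                disp=0, warn_convergence=False)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(str(exc)) from exc
        except (np.linalg.LinAlgError, RuntimeWarning) as exc:
            raise SeparationError(
                f"{self.outcome} ~ {self.exposure}: singular/overflowing fit "
                f"(likely separation): {exc}") from exc
        params = np.asarray(res.params, dtype=float)
        if not res.mle_retvals.get("converged", True):
            raise NonConvergenceError(
                f"{self.outcome} ~ {self.exposure}: no convergence in "
                f"{maxiter} iterations")
        fitted = np.asarray(res.predict())
        pinned = (np.all((fitted < 1e-8) | (fitted > 1 - 1e-8))
                  if self.kind == "binomial" else False)
        if np.max(np.abs(params)) > _SEPARATION_BETA or pinned:
            raise SeparationError(
                f"{self.outcome} ~ {self.exposure}: diverging coefficients "
                "(perfect or quasi-perfect separation)")
        return AssociationResults(self, res)


class AssociationResults:
    """Fitted estimates, uncertainties and diagnostics for one model."""

    def __init__(self, model: FrailtyAssociationModel, sm_results):
        self.model = model
        self._res = sm_results
        self.llf = float(sm_results.llf)
        self.params = np.asarray(sm_results.params, dtype=float)
        self.bse = np.asarray(sm_results.bse, dtype=float)
        self.n_used = model.n_used
        self.effects = self._collect_effects()

    def _collect_effects(self) -> list[AssociationResult]:
        m = self.model
        j = m.exog_names.index(m.exposure)
        out = []
        if m.kind == "binomial":
            b = float(self.params[j])
            se = float(self.bse[j])
            p = float(self._res.pvalues[j])
            out.append(AssociationResult(
                "OR", math.exp(b), math.exp(b - WALD_Z * se),
                math.exp(b + WALD_Z * se), se, p, m.n_used,
                m.outcome, m.exposure))
        else:
            params = np.atleast_2d(self.params)     # (k_exog, n_cats-1)
            bses = np.atleast_2d(self.bse)
            pvals = np.atleast_2d(np.asarray(self._res.pvalues))
            assert m.categories is not None
            for col, cat in enumerate(m.categories[1:]):
                b = float(params[j, col])
                se = float(bses[j, col])
                p = float(pvals[j, col])
                out.append(AssociationResult(
                    "RRR", math.exp(b), math.exp(b - WALD_Z * se),
                    math.exp(b + WALD_Z * se), se, p, m.n_used,
                    m.outcome, m.exposure, category=cat,
                    baseline_category=m.baseline))
        return out

    # -- reporting ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_dict() for e in self.effects])

    def predict_probability(self, exog: np.ndarray | None = None) -> np.ndarray:
        """Fitted outcome probabilities (rows sum to 1 for the multinomial)."""
        p = np.asarray(self._res.predict(exog))
        if self.model.kind == "multinomial" and p.ndim == 1:
            p = p.reshape(1, -1)
        return p

    def summary(self) -> str:
        m = self.model
        label = "odds ratio (OR)" if m.kind == "binomial" else "relative risk ratio (RRR)"
        lines = [
            "Frailty-voice association model",
            "=" * 64,
            f"Outcome:   {m.outcome}",
            f"Exposure:  {m.exposure} (per "
            + ("SD" if m.exposure_scale != 1.0 else "unit") + ")",
            f"Model:     {'binomial logit' if m.kind == 'binomial' else 'multinomial logit'}"
            + (f", baseline = {m.baseline}" if m.baseline else ""),
            f"N used:    {self.n_used}    log-likelihood: {self.llf:.3f}",
            "-" * 64,
            f"{'contrast':<12}{label.split()[-1].strip('()'):>8}"
            f"{'95% CI':>19}{'SE(log)':>9}{'p':>9}",
        ]
        for e in self.effects:
            contrast = e.category or "frail"
            lines.append(
                f"{contrast:<12}{e.estimate:>8.3f}"
                f"   [{e.ci_low:7.3f},{e.ci_high:8.3f}]"
                f"{e.se_log:>9.3f}{e.p_value:>9.4f}")
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot_effects(self, ax=None):
        """Forest plot of the fitted effect(s) with 95% CIs (log scale)."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 1 + 0.6 * len(self.effects)))
        ys = np.arange(len(self.effects))[::-1]
        for y, e in zip(ys, self.effects):
            ax.plot([e.ci_low, e.ci_high], [y, y], "-", color="0.4")
            ax.plot([e.estimate], [y], "s", color="C0")
        ax.axvline(1.0, color="0.7", ls="--")
        ax.set_xscale("log")
        ax.set_yticks(ys)
        ax.set_yticklabels([e.category or e.outcome for e in self.effects])
        ax.set_xlabel(f"{self.effects[0].effect_type} per unit {self.model.exposure}")
        return ax


# -- functional wrappers ---------------------------------------------------

def fit_binomial(spec: ModelSpec, data: pd.DataFrame) -> AssociationResult:
    """Fit one binomial logistic model; returns its single OR effect."""
    if spec.outcome == MULTINOMIAL_OUTCOME:
        raise ConfigurationError("use fit_multinomial for the 4-category outcome")
    return FrailtyAssociationModel.from_spec(spec, data).fit().effects[0]


def fit_multinomial(spec: ModelSpec, data: pd.DataFrame,
                    baseline: str = "nonfrail") -> list[AssociationResult]:
    """Fit the 4-category multinomial model; one RRR per non-baseline category."""
    model = FrailtyAssociationModel.from_dataframe(
        data, MULTINOMIAL_OUTCOME, spec.exposure, covariates=spec.covariates,
        standardize_exposure=spec.standardize_exposure, baseline=baseline)
    return model.fit().effects
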