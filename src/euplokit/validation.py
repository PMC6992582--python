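"""Evaluation machinery: holdout split, ROC/AUC, generalized R-squared,
model-vs-model comparison, predictive-value contingency tables, the
Tukey-Kramer sensitivity check, and the end-to-end validation pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
from scipy import stats

from .calculator import (
    CoefficientSet,
    PatientProfile,
    euploidy_probability,
    linear_predictor,
    mii_min,
)
from .cohort import PatientRecord
from .errors import DomainError, StageError
from .fitting import (
    LogitFit,
    adaptive_lasso_nb,
    fit_binomial_logit,
    fit_count_distribution,
)

__all__ = [
    "HoldoutSplit",
    "PPVTable",
    "ModelComparison",
    "PipelineConfig",
    "ValidationReport",
    "holdout_split",
    "auc",
    "generalized_r2",
    "compare_models",
    "ppv_table",
    "tukey_hsd",
    "run_validation_pipeline",
]


# ---------------------------------------------------------------------------
# holdout split


@dataclass(frozen=True)
class HoldoutSplit:
    train_ids: tuple[str, ...]
    valid_ids: tuple[str, ...]
    fraction: float
    seed: int


def holdout_split(
    records: Sequence[PatientRecord], fraction: float = 0.75, seed: int = 0
) -> HoldoutSplit:
    """Simple random split into training/validation id sets.

    The training set size is ``round(fraction * n)``; the split is
    reproducible from the seed and unstratified.
    """
    if not (0.0 < fraction < 1.0):
        raise DomainError(f"fraction must lie in (0, 1), got {fraction}")
    n = len(records)
    if n < 8:
        raise DomainError(f"need at least 8 records to split, got {n}")
    ids = [r.patient_id for r in records]
    n_train = round(fraction * n)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = sorted(ids[i] for i in order[:n_train])
    valid = sorted(ids[i] for i in order[n_train:])
    return HoldoutSplit(tuple(train), tuple(valid), fraction, seed)


# ---------------------------------------------------------------------------
# discrimination / fit metrics


def auc(scores: Sequence[float], outcomes: Sequence[int]) -> float:
    """Area under the ROC curve via the tie-corrected Mann-Whitney statistic."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes)
    if s.shape != y.shape or s.ndim != 1:
        raise DomainError("scores and outcomes must be 1-D and equal length")
    if not np.all((y == 0) | (y == 1)):
        raise DomainError("outcomes must be 0/1")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DomainError("both outcome classes must be present")
    ranks = stats.rankdata(s)
    rank_sum_pos = float(ranks[y == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def generalized_r2(loglik_null: float, loglik_model: float, n_rows: int) -> float:
    """Generalized (Nagelkerke/Cragg-Uhler) R-squared.

    ``[1 - exp(2(ll0 - ll1)/n)] / [1 - exp(2*ll0/n)]``; equals 0 when the
    model adds nothing and 1 for a saturated binary model (``ll1 = 0``).
    """
    if n_rows <= 0:
        raise DomainError(f"n_rows must be positive, got {n_rows}")
    if loglik_model < loglik_null - 1e-9:
        raise DomainError("model log-likelihood cannot be below the null log-likelihood")
    cox_snell = 1.0 - math.exp(2.0 * (loglik_null - loglik_model) / n_rows)
    max_r2 = 1.0 - math.exp(2.0 * loglik_null / n_rows)
    if max_r2 <= 0.0:
        return 0.0
    return cox_snell / max_r2


# ---------------------------------------------------------------------------
# model-vs-model comparison


@dataclass(frozen=True)
class ModelComparison:
    """Agreement between two coefficient sets over an evaluation set.

    Correlations are ``None`` when a prediction vector has zero variance.
    """

    pearson_p: float | None
    spearman_p: float | None
    mii_pearson: dict[float, float | None]
    median_abs_dp: float
    mean_abs_dp: float
    n_profiles: int

    def to_dict(self) -> dict[str, Any]:
        return {
            "pearson_p": self.pearson_p,
            "spearman_p": self.spearman_p,
            "mii_pearson": {str(k): v for k, v in self.mii_pearson.items()},
            "median_abs_dp": self.median_abs_dp,
            "mean_abs_dp": self.mean_abs_dp,
            "n_profiles": self.n_profiles,
        }


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    # ptp, not std: the mean of identical floats can round, leaving a
    # spurious nonzero standard deviation
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def compare_models(
    coefs_a: CoefficientSet,
    coefs_b: CoefficientSet,
    eval_profiles: Sequence[PatientProfile],
    pi_levels: Sequence[float] = (0.7, 0.8, 0.9),
) -> ModelComparison:
    """Pearson/Spearman correlation of predicted p, per-pi correlation of
    the minimum MII counts, and the absolute probability differences."""
    if len(eval_profiles) < 10:
        raise DomainError(f"need at least 10 evaluation profiles, got {len(eval_profiles)}")
    p_a = np.array([euploidy_probability(linear_predictor(pr, coefs_a)) for pr in eval_profiles])
    p_b = np.array([euploidy_probability(linear_predictor(pr, coefs_b)) for pr in eval_profiles])
    if np.ptp(p_a) == 0 or np.ptp(p_b) == 0:
        spearman = None
    else:
        spearman = float(stats.spearmanr(p_a, p_b).statistic)
    mii_corr: dict[float, float | None] = {}
    for pi in pi_levels:
        mii_a = np.array([mii_min(p, pi).mii_min for p in p_a], dtype=float)
        mii_b = np.array([mii_min(p, pi).mii_min for p in p_b], dtype=float)
        mii_corr[pi] = _safe_pearson(mii_a, mii_b)
    dp = np.abs(p_a - p_b)
    return ModelComparison(
        pearson_p=_safe_pearson(p_a, p_b),
        spearman_p=spearman,
        mii_pearson=mii_corr,
        median_abs_dp=float(np.median(dp)),
        mean_abs_dp=float(np.mean(dp)),
        n_profiles=len(eval_profiles),
    )


# ---------------------------------------------------------------------------
# predictive-value tables


@dataclass(frozen=True)
class PPVTable:
    """2x2 cross-tabulation {reached minimum-MII yes/no} x {>=1 euploid yes/no}.

    ``ppv`` is the percentage with at least one euploid blastocyst among
    patients who reached the predicted minimum count; ``None`` when the
    reached row is empty.
    """

    pi: float
    reached_success: int
    reached_failure: int
    not_reached_success: int
    not_reached_failure: int

    @classmethod
    def from_counts(
        cls,
        pi: float,
        reached_success: int,
        reached_failure: int,
        not_reached_success: int = 0,
        not_reached_failure: int = 0,
    ) -> "PPVTable":
        return cls(pi, reached_success, reached_failure, not_reached_success, not_reached_failure)

    @property
    def n(self) -> int:
        return (
            self.reached_success
            + self.reached_failure
            + self.not_reached_success
            + self.not_reached_failure
        )

    @property
    def n_reached(self) -> int:
        return self.reached_success + self.reached_failure

    @property
    def ppv(self) -> float | None:
        if self.n_reached == 0:
            return None
        return 100.0 * self.reached_success / self.n_reached

    @property
    def not_reached_success_rate(self) -> float | None:
        total = self.not_reached_success + self.not_reached_failure
        if total == 0:
            return None
        return 100.0 * self.not_reached_success / total

    def to_dict(self) -> dict[str, Any]:
        return {
            "pi": self.pi,
            "counts": {
                "reached_success": self.reached_success,
                "reached_failure": self.reached_failure,
                "not_reached_success": self.not_reached_success,
                "not_reached_failure": self.not_reached_failure,
            },
            "n": self.n,
            "ppv_pct": self.ppv,
            "not_reached_success_pct": self.not_reached_success_rate,
        }


def ppv_table(
    records: Sequence[PatientRecord], coefs: CoefficientSet, pi: float
) -> PPVTable:
    """Cross-tabulate reaching the predicted minimum MII count against
    obtaining at least one euploid blastocyst.

    A patient "reached" when the observed retrieved MII count is at least
    the model-predicted minimum for the requested success probability.
    """
    if not records:
        raise DomainError("empty cohort")
    counts = [0, 0, 0, 0]  # rs, rf, ns, nf
    for r in records:
        p = euploidy_probability(linear_predictor(r.profile, coefs))
        needed = mii_min(p, pi).mii_min
        reached = r.n_mii >= needed
        success = r.n_euploid >= 1
        idx = (0 if reached else 2) + (0 if success else 1)
        counts[idx] += 1
    return PPVTable(pi, *counts)


# ---------------------------------------------------------------------------
# Tukey-Kramer HSD


@dataclass(frozen=True)
class TukeyComparison:
    group_a: str
    group_b: str
    mean_difference: float
    ci_lower: float
    ci_upper: float
    pvalue: float
    significant: bool


def tukey_hsd(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> list[TukeyComparison]:
    """All pairwise mean comparisons with the studentized-range criterion,
    using the Kramer adjustment for unequal group sizes."""
    labels = list(groups)
    if len(labels) < 2:
        raise DomainError("need at least 2 groups")
    arrays = [np.asarray(groups[label], dtype=float) for label in labels]
    if any(a.size < 2 for a in arrays):
        raise DomainError("every group needs at least 2 observations")
    if all(np.var(a) == 0 for a in arrays):
        raise DomainError("zero within-group variance in all groups")
    res = stats.tukey_hsd(*arrays)
    ci = res.confidence_interval(confidence_level=1.0 - alpha)
    out: list[TukeyComparison] = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out.append(
                TukeyComparison(
                    group_a=labels[i],
                    group_b=labels[j],
                    mean_difference=float(res.statistic[i, j]),
                    ci_lower=float(ci.low[i, j]),
                    ci_upper=float(ci.high[i, j]),
                    pvalue=float(res.pvalue[i, j]),
                    significant=bool(res.pvalue[i, j] < alpha),
                )
            )
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs for :func:`run_validation_pipeline`."""

    fraction: float = 0.75
    seed: int = 0
    pi_levels: tuple[float, ...] = (0.7, 0.8, 0.9)
    include_center: bool = True
    force_sperm: bool = True
    lasso_candidates: tuple[str, ...] = ("age", "d1", "d2", "e1", "e2")
    lasso_grid_size: int = 100
    auc_mode: str = "oocyte"  # or "patient"
    reference: CoefficientSet | None = None

    def to_dict(self) -> dict[str, Any]:
        return {
            "fraction": self.fraction,
            "seed": self.seed,
            "pi_levels": list(self.pi_levels),
            "include_center": self.include_center,
            "force_sperm": self.force_sperm,
            "lasso_candidates": list(self.lasso_candidates),
            "lasso_grid_size": self.lasso_grid_size,
            "auc_mode": self.auc_mode,
            "reference": None if self.reference is None else self.reference.to_dict(),
        }


@dataclass
class ValidationReport:
    """Aggregated output of the full validation pipeline; JSON round-trips."""

    config: dict[str, Any]
    n_patients: int
    count_distribution: dict[str, Any]
    lasso: dict[str, Any]
    logit: dict[str, Any]
    coefficients: dict[str, Any]
    metrics: dict[str, Any]
    mii_min_summary: dict[str, Any]
    comparison: dict[str, Any] | None
    ppv_tables: list[dict[str, Any]]

    def to_dict(self) -> dict[str, Any]:
        return {
            "config": self.config,
            "n_patients": self.n_patients,
            "count_distribution": self.count_distribution,
            "lasso": self.lasso,
            "logit": self.logit,
            "coefficients": self.coefficients,
            "metrics": self.metrics,
            "mii_min_summary": self.mii_min_summary,
            "comparison": self.comparison,
            "ppv_tables": self.ppv_tables,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ValidationReport":
        return cls(**{k: data[k] for k in (
            "config",
            "n_patients",
            "count_distribution",
            "lasso",
            "logit",
            "coefficients",
            "metrics",
            "mii_min_summary",
            "comparison",
            "ppv_tables",
        )})


def _oocyte_scores(
    records: Sequence[PatientRecord], coefs: CoefficientSet
) -> tuple[np.ndarray, np.ndarray]:
    scores: list[float] = []
    outcomes: list[int] = []
    for r in records:
        if r.n_mii < 1:
            continue
        p = euploidy_probability(linear_predictor(r.profile, coefs))
        scores.extend([p] * r.n_mii)
        outcomes.extend([1] * r.n_euploid + [0] * (r.n_mii - r.n_euploid))
    return np.array(scores), np.array(outcomes)


def _patient_scores(
    records: Sequence[PatientRecord], coefs: CoefficientSet
) -> tuple[np.ndarray, np.ndarray]:
    scores: list[float] = []
    outcomes: list[int] = []
    for r in records:
        p = euploidy_probability(linear_predictor(r.profile, coefs))
        scores.append(-math.expm1(r.n_mii * math.log1p(-p)))
        outcomes.append(int(r.n_euploid >= 1))
    return np.array(scores), np.array(outcomes)


def _subset_metrics(
    records: Sequence[PatientRecord], fit: LogitFit, mode: str
) -> dict[str, Any]:
    score_fn = _oocyte_scores if mode == "oocyte" else _patient_scores
    scores, outcomes = score_fn(records, fit.coefficients)
    # per-oocyte Bernoulli log-likelihoods for the generalized R-squared
    m = np.array([r.n_euploid for r in records if r.n_mii >= 1], dtype=float)
    N = np.array([r.n_mii for r in records if r.n_mii >= 1], dtype=float)
    p = np.array(
        [
            euploidy_probability(linear_predictor(r.profile, fit.coefficients))
            for r in records
            if r.n_mii >= 1
        ]
    )
    p = np.clip(p, 1e-12, 1 - 1e-12)
    ll = float(np.sum(m * np.log(p) + (N - m) * np.log1p(-p)))
    pbar = m.sum() / N.sum()
    ll0 = float(np.sum(m * math.log(pbar) + (N - m) * math.log1p(-pbar)))
    n_units = int(N.sum())
    return {
        "auc": auc(scores, outcomes),
        "generalized_r2": generalized_r2(ll0, max(ll, ll0), n_units),
        "n_patients": int(len([r for r in records if r.n_mii >= 1])),
        "n_oocytes": n_units,
    }


def run_validation_pipeline(
    records: Sequence[PatientRecord], config: PipelineConfig
) -> ValidationReport:
    """Run the staged validation roadmap on a CRF cohort.

    Stages, in order: count-distribution identification; adaptive-Lasso
    covariate selection; final logistic fit on the training split;
    AUC / generalized R-squared on training and validation splits;
    minimum-MII summaries at the configured success levels; optional
    comparison with a reference coefficient set; predictive-value tables
    on the validation split.  Any stage failure raises
    :class:`~euplokit.errors.StageError` naming the stage.
    """
    if not records:
        raise StageError("input", "empty cohort")
    by_id = {r.patient_id: r for r in records}

    try:
        nb = fit_count_distribution([r.n_euploid for r in records])
    except Exception as exc:
        raise StageError("count_distribution", exc) from exc

    try:
        path = adaptive_lasso_nb(
            records, list(config.lasso_candidates), grid_size=config.lasso_grid_size
        )
    except Exception as exc:
        raise StageError("lasso_selection", exc) from exc

    try:
        split = holdout_split(records, config.fraction, config.seed)
        train = [by_id[i] for i in split.train_ids]
        valid = [by_id[i] for i in split.valid_ids]
    except Exception as exc:
        raise StageError("holdout_split", exc) from exc

    try:
        fit = fit_binomial_logit(
            train, include_center=config.include_center, label="pipeline-fit"
        )
    except Exception as exc:
        raise StageError("logit_fit", exc) from exc

    try:
        metrics = {
            "training": _subset_metrics(train, fit, config.auc_mode),
            "validation": _subset_metrics(valid, fit, config.auc_mode),
            "auc_mode": config.auc_mode,
        }
    except Exception as exc:
        raise StageError("metrics", exc) from exc

    try:
        mii_summary: dict[str, Any] = {}
        p_valid = np.array(
            [
                euploidy_probability(linear_predictor(r.profile, fit.coefficients))
                for r in valid
            ]
        )
        for pi in config.pi_levels:
            counts = np.array([mii_min(float(p), pi).mii_min for p in p_valid])
            mii_summary[str(pi)] = {
                "mean": float(counts.mean()),
                "median": float(np.median(counts)),
                "min": int(counts.min()),
                "max": int(counts.max()),
            }
    except Exception as exc:
        raise StageError("mii_min", exc) from exc

    comparison = None
    if config.reference is not None:
        try:
            comparison = compare_models(
                fit.coefficients,
                config.reference,
                [r.profile for r in valid],
                config.pi_levels,
            ).to_dict()
        except Exception as exc:
            raise StageError("model_comparison", exc) from exc

    try:
        ref_for_ppv = config.reference if config.reference is not None else fit.coefficients
        tables = [ppv_table(valid, ref_for_ppv, pi).to_dict() for pi in config.pi_levels]
    except Exception as exc:
        raise StageError("ppv_tables", exc) from exc

    return ValidationReport(
        config=config.to_dict(),
        n_patients=len(records),
        count_distribution=nb.to_dict(),
        lasso=path.summary(),
        logit=fit.summary(),
        coefficients=fit.coefficients.to_dict(),
        metrics=metrics,
        mii_min_summary=mii_summary,
        comparison=comparison,
        ppv_tables=tables,
    )
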