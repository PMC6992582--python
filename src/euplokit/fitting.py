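"""Model-fitting stages: count-distribution identification, adaptive-Lasso
covariate selection on the euploid-count response, and the final
oocyte-level binomial logistic fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.stats import nbinom, poisson
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .calculator import CoefficientSet, effect_codes
from .cohort import PatientRecord
from .errors import FitError, SeparationError

__all__ = [
    "NBFit",
    "LassoPath",
    "LogitFit",
    "fit_count_distribution",
    "adaptive_lasso_nb",
    "fit_binomial_logit",
    "records_to_frame",
    "expand_records",
]

_COEF_NAMES = (
    "intercept",
    "b_ej_noa_age",
    "b_surg_noa_age",
    "s_ej_noa",
    "g_anat_andro",
    "g_gen_anat",
)


def _aicc(loglik: float, k: int, n: int) -> float:
    aic = -2.0 * loglik + 2.0 * k
    if n - k - 1 <= 0:
        return math.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# count-distribution identification


@dataclass(frozen=True)
class NBFit:
    """Negative-binomial MLE for a count vector, with Poisson comparison.

    ``preferred`` is ``"negative_binomial"`` when its AICc is lower than the
    Poisson AICc.  ``boundary`` flags degenerate inputs (all counts equal)
    or a dispersion estimate diverging to the Poisson limit.
    """

    mu: float
    k: float
    loglik: float
    aicc: float
    poisson_loglik: float
    poisson_aicc: float
    preferred: str
    boundary: bool = False

    def to_dict(self) -> dict[str, Any]:
        return {
            "mu": self.mu,
            "k": None if math.isinf(self.k) else self.k,
            "loglik": None if math.isnan(self.loglik) else self.loglik,
            "aicc": None if math.isnan(self.aicc) else self.aicc,
            "poisson_loglik": self.poisson_loglik,
            "poisson_aicc": self.poisson_aicc,
            "preferred": self.preferred,
            "boundary": self.boundary,
        }


#: above this dispersion estimate the NB fit is flagged as the Poisson boundary
_K_BOUNDARY = 1e6


def fit_count_distribution(counts: Sequence[int]) -> NBFit:
    """Maximum-likelihood negative-binomial fit (mean ``mu``, size ``k``,
    variance ``mu + mu**2/k``) with a Poisson AICc comparison.
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 30:
        raise FitError(f"need at least 30 counts, got {x.size}")
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise FitError("counts must be non-negative integers")
    n = x.size
    mean = float(x.mean())

    pois_ll = float(poisson.logpmf(x, max(mean, 1e-12)).sum())
    pois_aicc = _aicc(pois_ll, 1, n)

    if np.all(x == x[0]):
        return NBFit(
            mu=mean,
            k=math.inf,
            loglik=math.nan,
            aicc=math.nan,
            poisson_loglik=pois_ll,
            poisson_aicc=pois_aicc,
            preferred="poisson",
            boundary=True,
        )

    var = float(x.var(ddof=1))
    k0 = mean**2 / (var - mean) if var > mean else 100.0

    def negll(theta: np.ndarray) -> float:
        mu, k = np.exp(theta)
        return -float(nbinom.logpmf(x, k, k / (k + mu)).sum())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(
            negll,
            x0=np.log([max(mean, 1e-6), max(k0, 1e-3)]),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
    mu_hat, k_hat = np.exp(res.x)
    nb_ll = -float(res.fun)
    nb_aicc = _aicc(nb_ll, 2, n)
    boundary = bool(k_hat > _K_BOUNDARY)
    preferred = "negative_binomial" if nb_aicc < pois_aicc else "poisson"
    return NBFit(
        mu=float(mu_hat),
        k=float(k_hat),
        loglik=nb_ll,
        aicc=nb_aicc,
        poisson_loglik=pois_ll,
        poisson_aicc=pois_aicc,
        preferred=preferred,
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# covariate frame helpers


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Per-patient covariate frame with the contrast codes expanded.

    Columns: ``age`` (raw years), the sperm contrasts ``d1``/``d2``, the
    center contrasts ``e1``/``e2``, and the response pair ``n_mii``/``n_euploid``.
    """
    rows = []
    for r in records:
        d1, d2, e1, e2 = effect_codes(r.sperm_source, r.center)
        rows.append(
            {
                "patient_id": r.patient_id,
                "age": r.female_age,
                "d1": d1,
                "d2": d2,
                "e1": e1,
                "e2": e2,
                "n_mii": r.n_mii,
                "n_euploid": r.n_euploid,
            }
        )
    return pd.DataFrame(rows)


def expand_records(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """One row per MII oocyte with a 0/1 euploid outcome.

    Each patient contributes ``n_mii`` rows, ``n_euploid`` of which carry
    outcome 1; patients with no MII oocytes contribute nothing.
    """
    frame = records_to_frame(records)
    frame = frame[frame["n_mii"] >= 1]
    reps = frame["n_mii"].to_numpy()
    expanded = frame.loc[frame.index.repeat(reps)].reset_index(drop=True)
    outcome = np.zeros(int(reps.sum()), dtype=int)
    offset = 0
    for n, m in zip(frame["n_mii"], frame["n_euploid"]):
        outcome[offset : offset + m] = 1
        offset += n
    expanded["euploid"] = outcome
    return expanded.drop(columns=["n_mii", "n_euploid"])


# ---------------------------------------------------------------------------
# adaptive Lasso selection (negative-binomial log-link, offset log N)


@dataclass(frozen=True)
class LassoPath:
    """Penalty path of the adaptive-Lasso selection stage."""

    candidates: tuple[str, ...]
    alphas: np.ndarray
    coefficients: np.ndarray  # shape (n_grid, n_candidates); NaN = skipped
    aiccs: np.ndarray  # NaN = skipped
    selected: tuple[str, ...]
    adaptive_weights: dict[str, float]
    offset_mode: str
    dropped_duplicates: tuple[str, ...] = ()
    n_used: int = 0

    def summary(self) -> dict[str, Any]:
        ok = np.isfinite(self.aiccs)
        return {
            "candidates": list(self.candidates),
            "selected": list(self.selected),
            "n_grid": int(self.alphas.size),
            "n_converged": int(ok.sum()),
            "best_aicc": float(np.nanmin(self.aiccs)) if ok.any() else None,
            "offset_mode": self.offset_mode,
            "dropped_duplicates": list(self.dropped_duplicates),
            "n_used": self.n_used,
        }


def adaptive_lasso_nb(
    data: Sequence[PatientRecord] | pd.DataFrame,
    candidates: Sequence[str],
    *,
    grid_size: int = 100,
    grid_decades: float = 4.0,
    offset_mode: str = "offset",
    count_col: str = "n_euploid",
    exposure_col: str = "n_mii",
    parsimony_margin: float = 2.0,
) -> LassoPath:
    """Adaptive-Lasso covariate selection for the euploid-count response.

    Negative-binomial log-link regression of the count on standardized
    candidates, adjusting for the number of MII oocytes either as an
    offset ``log(N)`` (default) or as an extra unpenalized covariate
    (``offset_mode="covariate"``).  Adaptive weights ``1/|beta~|`` come
    from an unpenalized fixed-dispersion initial fit; the path is solved
    by coordinate descent over a log-spaced penalty grid with the NB
    dispersion held fixed at a moment estimate.

    The selected set is the support at minimum AICc, except that any
    sparser support whose AICc lies within ``parsimony_margin`` of the
    minimum is preferred (models within ~2 information-criterion units
    are indistinguishable, so the tie breaks toward parsimony).
    Zero-MII patients are excluded.
    """
    if len(candidates) < 2:
        raise FitError("need at least 2 candidate covariates")
    if offset_mode not in ("offset", "covariate"):
        raise FitError(f"unknown offset_mode {offset_mode!r}")
    frame = data if isinstance(data, pd.DataFrame) else records_to_frame(data)
    frame = frame[frame[exposure_col] >= 1].reset_index(drop=True)
    n = len(frame)
    if n < 10:
        raise FitError(f"need at least 10 usable records, got {n}")
    missing = [c for c in candidates if c not in frame.columns]
    if missing:
        raise FitError(f"candidate columns not in data: {missing}")

    y = frame[count_col].to_numpy(dtype=float)
    exposure = frame[exposure_col].to_numpy(dtype=float)

    # standardize candidates; constant columns get a zero column (never selected)
    X = frame[list(candidates)].to_numpy(dtype=float)
    mu_x = X.mean(axis=0)
    sd_x = X.std(axis=0)
    sd_x[sd_x == 0] = 1.0
    Z = (X - mu_x) / sd_x

    # collinearity contract: exact duplicates keep the first occurrence only
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(Z.shape[1]):
        dup = any(np.allclose(Z[:, j], Z[:, i]) or np.allclose(Z[:, j], -Z[:, i]) for i in keep)
        if dup:
            dropped.append(candidates[j])
        else:
            keep.append(j)
    kept_names = [candidates[j] for j in keep]
    Zk = Z[:, keep]
    p = Zk.shape[1]

    if offset_mode == "offset":
        exog = sm.add_constant(Zk, has_constant="add")
        offset = np.log(exposure)
        unpenalized = 1  # constant
    else:
        exog = sm.add_constant(
            np.column_stack([np.log(exposure), Zk]), has_constant="add"
        )
        offset = None
        unpenalized = 2  # constant + log-exposure adjustment

    # NB dispersion estimated once by the Cameron-Trivedi moment estimator
    # on Poisson fitted values, then held fixed along the penalty path
    # (glmnet-style: the path solver only profiles the mean model).
    with warnings.catch_warnings(record=True):
        warnings.simplefilter("ignore")
        pois = sm.GLM(y, exog, family=sm.families.Poisson(), offset=offset).fit()
    mu_hat = np.asarray(pois.fittedvalues)
    disp = float(((y - mu_hat) ** 2 - mu_hat).sum() / (mu_hat**2).sum())
    if disp > 1e-6:
        family = sm.families.NegativeBinomial(alpha=disp)
    else:  # no overdispersion: use the Poisson limit directly
        disp = 0.0
        family = sm.families.Poisson()

    def fit_support(cols: np.ndarray) -> Any:
        with warnings.catch_warnings(record=True):
            warnings.simplefilter("ignore")
            return sm.GLM(y, cols, family=family, offset=offset).fit()

    # adaptive weights 1/|beta~| from the unpenalized fixed-dispersion fit
    init = fit_support(exog)
    beta0 = np.asarray(init.params)[unpenalized : unpenalized + p]
    if not np.all(np.isfinite(beta0)):
        beta0 = np.asarray(pois.params)[unpenalized : unpenalized + p]
    weights = 1.0 / np.maximum(np.abs(beta0), 1e-8)

    # penalty entry point from the score at the exposure-adjusted null rate
    null_rate = y.sum() / exposure.sum()
    resid = y - null_rate * exposure
    score = np.abs(Zk.T @ resid) / weights
    alpha_max = 1.2 * float(score.max()) / n if score.max() > 0 else 1.0
    alphas = np.logspace(
        math.log10(alpha_max), math.log10(alpha_max) - grid_decades, grid_size
    )

    # AICc per grid point from an unpenalized refit on the active support
    # (debiased criterion): each retained covariate costs a full degree of
    # freedom regardless of how far the lasso shrank it.
    def support_loglik(support: tuple[int, ...]) -> float:
        cols = [np.ones(n)] if offset_mode == "offset" else [np.ones(n), np.log(exposure)]
        cols += [Zk[:, j] for j in support]
        return float(fit_support(np.column_stack(cols)).llf)

    loglik_cache: dict[tuple[int, ...], float] = {}
    coefs = np.full((grid_size, p), np.nan)
    aiccs = np.full(grid_size, np.nan)
    start = None  # warm start along the path, strongest penalty first
    for g, alpha in enumerate(alphas):
        alpha_vec = np.zeros(exog.shape[1])
        alpha_vec[unpenalized : unpenalized + p] = alpha * weights
        try:
            with warnings.catch_warnings(record=True):
                warnings.simplefilter("ignore")
                res = sm.GLM(y, exog, family=family, offset=offset).fit_regularized(
                    method="elastic_net",
                    alpha=alpha_vec,
                    L1_wt=1.0,
                    start_params=start,
                    cnvrg_tol=1e-7,
                )
            params = np.asarray(res.params)
            if not np.all(np.isfinite(params)):
                raise FitError("non-finite solution")
            beta = params[unpenalized : unpenalized + p]
            start = params
            support = tuple(j for j in range(p) if abs(beta[j]) > 1e-8)
            if support not in loglik_cache:
                loglik_cache[support] = support_loglik(support)
            loglik = loglik_cache[support]
        except Exception as exc:  # non-convergence: skip the grid point
            warnings.warn(f"penalty grid point {g} skipped: {exc}", stacklevel=2)
            continue
        coefs[g] = beta
        # + dispersion: held fixed but estimated from the data
        aiccs[g] = _aicc(loglik, len(support) + unpenalized + 1, n)

    if not np.any(np.isfinite(aiccs)):
        raise FitError("no penalty grid point converged")
    best = int(np.nanargmin(aiccs))
    threshold = aiccs[best] + parsimony_margin
    best_support_size = int(np.sum(np.abs(coefs[best]) > 1e-8))
    for g in range(grid_size):
        if not np.isfinite(aiccs[g]) or aiccs[g] > threshold:
            continue
        size = int(np.sum(np.abs(coefs[g]) > 1e-8))
        if size < best_support_size or (
            size == best_support_size and aiccs[g] < aiccs[best]
        ):
            best, best_support_size = g, size
    selected = tuple(
        kept_names[j] for j in range(p) if abs(coefs[best, j]) > 1e-8
    )
    return LassoPath(
        candidates=tuple(candidates),
        alphas=alphas,
        coefficients=coefs,
        aiccs=aiccs,
        selected=selected,
        adaptive_weights=dict(zip(kept_names, weights.tolist())),
        offset_mode=offset_mode,
        dropped_duplicates=tuple(dropped),
        n_used=n,
    )


# ---------------------------------------------------------------------------
# final binomial logistic fit


@dataclass(frozen=True)
class LogitFit:
    """Oocyte-level binomial logistic fit packaged as a CoefficientSet.

    ``loglik``/``loglik_null`` are on the per-oocyte Bernoulli scale
    (no binomial coefficient term), so aggregated and expanded
    representations of the same cohort give identical values.
    """

    coefficients: CoefficientSet
    stderr: dict[str, float]
    cov: np.ndarray
    loglik: float
    loglik_null: float
    n_rows: int
    n_oocytes: int
    converged: bool

    def summary(self) -> dict[str, Any]:
        return {
            "label": self.coefficients.label,
            "coefficients": {
                k: v
                for k, v in self.coefficients.to_dict().items()
                if k in _COEF_NAMES or k == "age_center"
            },
            "stderr": dict(self.stderr),
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "n_rows": self.n_rows,
            "n_oocytes": self.n_oocytes,
            "converged": self.converged,
        }


def _bernoulli_loglik(m: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-300, 1 - 1e-16)
    return float(np.sum(m * np.log(p) + (n - m) * np.log1p(-p)))


def fit_binomial_logit(
    records: Sequence[PatientRecord],
    *,
    include_center: bool = True,
    age_center: float | None = None,
    representation: str = "aggregated",
    label: str = "refit",
) -> LogitFit:
    """Fit the contrast-coded logistic model to the (m, N) response pairs.

    Age is centered at ``age_center`` (default: mean female age of the
    fitting records, computed over patients with at least one MII oocyte).
    ``representation`` switches between the aggregated two-column binomial
    response and the expanded per-oocyte 0/1 response; the MLE is identical.
    """
    if representation not in ("aggregated", "expanded"):
        raise FitError(f"unknown representation {representation!r}")
    usable = [r for r in records if r.n_mii >= 1]
    if len(usable) < 2:
        raise FitError(f"need at least 2 records with MII oocytes, got {len(usable)}")

    m = np.array([r.n_euploid for r in usable], dtype=float)
    N = np.array([r.n_mii for r in usable], dtype=float)
    if m.sum() == 0 or (N - m).sum() == 0:
        raise SeparationError(
            "all-or-none response: every oocyte has the same outcome; "
            "the logistic MLE does not exist"
        )

    c = float(np.mean([r.female_age for r in usable])) if age_center is None else age_center
    codes = np.array([effect_codes(r.sperm_source, r.center) for r in usable], dtype=float)
    age_dev = np.array([r.female_age for r in usable]) - c
    cols = [codes[:, 0] * age_dev, codes[:, 1] * age_dev, codes[:, 0]]
    names = ["b_ej_noa_age", "b_surg_noa_age", "s_ej_noa"]
    if include_center:
        cols += [codes[:, 2], codes[:, 3]]
        names += ["g_anat_andro", "g_gen_anat"]
    X = sm.add_constant(np.column_stack(cols), has_constant="add")
    names = ["intercept"] + names

    if representation == "aggregated":
        endog = np.column_stack([m, N - m])
        exog = X
    else:
        reps = N.astype(int)
        exog = np.repeat(X, reps, axis=0)
        outcome = np.zeros(int(reps.sum()))
        offset = 0
        for ni, mi in zip(reps, m.astype(int)):
            outcome[offset : offset + mi] = 1.0
            offset += ni
        endog = outcome

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    except PerfectSeparationError as exc:
        raise SeparationError(str(exc)) from exc
    if not np.all(np.isfinite(result.params)) or not np.all(np.isfinite(result.bse)):
        raise SeparationError("non-finite estimates; likely separation or collinearity")

    params = dict(zip(names, result.params))
    stderr = dict(zip(names, result.bse))
    coefs = CoefficientSet(
        intercept=params["intercept"],
        age_center=c,
        b_ej_noa_age=params["b_ej_noa_age"],
        b_surg_noa_age=params["b_surg_noa_age"],
        s_ej_noa=params["s_ej_noa"],
        g_anat_andro=params.get("g_anat_andro", 0.0),
        g_gen_anat=params.get("g_gen_anat", 0.0),
        label=label,
        stderr=stderr,
    )
    p_hat = 1.0 / (1.0 + np.exp(-(X @ result.params)))
    loglik = _bernoulli_loglik(m, N, p_hat)
    p_null = m.sum() / N.sum()
    loglik_null = _bernoulli_loglik(m, N, np.full_like(m, p_null))
    return LogitFit(
        coefficients=coefs,
        stderr=stderr,
        cov=np.asarray(result.cov_params()),
        loglik=loglik,
        loglik_null=loglik_null,
        n_rows=len(usable),
        n_oocytes=int(N.sum()),
        converged=bool(getattr(result, "converged", True)),
    )
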