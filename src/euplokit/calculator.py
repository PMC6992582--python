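"""Per-oocyte euploidy-probability model and minimum-MII-oocyte estimator.

The probability model is a binomial logistic regression on three predictors
(female age, sperm source, treatment center) expressed through pairwise
indicator-difference contrasts.  Given the per-oocyte euploidy probability
``p`` and a target success probability ``pi``, the minimum number of mature
(MII) oocytes is the smallest integer ``N`` with ``1 - (1-p)**N >= pi``.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping

from .errors import CoefficientError, DomainError, ProfileError

__all__ = [
    "SpermSource",
    "Platform",
    "Center",
    "CoefficientSet",
    "PatientProfile",
    "EuploidyPrediction",
    "MIIEstimate",
    "default_coefficients",
    "effect_codes",
    "linear_predictor",
    "euploidy_probability",
    "mii_min",
    "predict",
    "probability_interval",
]

AGE_MIN = 18.0
AGE_MAX = 50.0

#: relative tolerance used when testing the success boundary of the
#: minimum-oocyte search; ceil(log(1-pi)/log(1-p)) is floating-point
#: fragile when the ratio lands near an integer.
_BOUNDARY_RTOL = 1e-9

#: beyond this the target is reported as unreachable rather than returning
#: an astronomically large count.
_MAX_MII = 10**9


class SpermSource(str, enum.Enum):
    """Sperm origin for ICSI, three modelled levels."""

    EJACULATE = "ejaculate"
    SURGICAL_NON_NOA = "surgical_non_noa"
    TESTICULAR_NOA = "testicular_noa"


class Platform(str, enum.Enum):
    NGS = "ngs"
    QPCR = "qpcr"
    NA = "na"


class Center(str, enum.Enum):
    """Treatment center; UNSPECIFIED contributes zero to the linear predictor."""

    ANATOLIA = "anatolia"
    ANDROFERT = "androfert"
    GENERA = "genera"
    UNSPECIFIED = "unspecified"

    @property
    def platform(self) -> Platform:
        if self is Center.GENERA:
            return Platform.QPCR
        if self in (Center.ANATOLIA, Center.ANDROFERT):
            return Platform.NGS
        return Platform.NA


_COEF_FIELDS = (
    "intercept",
    "b_ej_noa_age",
    "b_surg_noa_age",
    "s_ej_noa",
    "g_anat_andro",
    "g_gen_anat",
)


@dataclass(frozen=True)
class CoefficientSet:
    """Fitted logistic model on the indicator-difference contrast scale.

    Attributes
    ----------
    intercept
        Intercept ``a`` on the logit scale.
    age_center
        Centering constant ``c`` (years) subtracted from female age.
    b_ej_noa_age
        Coefficient of ``[I(ejaculate) - I(testicular NOA)] * (age - c)``.
    b_surg_noa_age
        Coefficient of ``[I(surgical non-NOA) - I(testicular NOA)] * (age - c)``.
    s_ej_noa
        Sperm-source main-effect contrast ``I(ejaculate) - I(testicular NOA)``.
    g_anat_andro, g_gen_anat
        Center contrasts; a set with both equal to zero is valid and
        corresponds to center-free prediction.
    stderr
        Optional per-coefficient standard errors (normal-approximation
        intervals only; coefficient covariances are not carried).
    """

    intercept: float
    age_center: float
    b_ej_noa_age: float
    b_surg_noa_age: float
    s_ej_noa: float
    g_anat_andro: float = 0.0
    g_gen_anat: float = 0.0
    label: str = ""
    platform_note: str = ""
    stderr: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        for name in _COEF_FIELDS + ("age_center",):
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or not math.isfinite(value):
                raise CoefficientError(f"coefficient '{name}' must be finite, got {value!r}")
        if not (AGE_MIN <= self.age_center <= AGE_MAX):
            raise CoefficientError(
                f"age_center must lie in [{AGE_MIN}, {AGE_MAX}], got {self.age_center}"
            )
        if self.stderr is not None:
            for name, value in self.stderr.items():
                if value is not None and value <= 0:
                    raise CoefficientError(f"standard error '{name}' must be positive")

    @property
    def center_free(self) -> bool:
        return self.g_anat_andro == 0.0 and self.g_gen_anat == 0.0

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "label": self.label,
            "intercept": self.intercept,
            "age_center": self.age_center,
            "b_ej_noa_age": self.b_ej_noa_age,
            "b_surg_noa_age": self.b_surg_noa_age,
            "s_ej_noa": self.s_ej_noa,
            "g_anat_andro": self.g_anat_andro,
            "g_gen_anat": self.g_gen_anat,
            "platform_note": self.platform_note,
        }
        if self.stderr is not None:
            out["stderr"] = dict(self.stderr)
        return out

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "CoefficientSet":
        missing = [k for k in ("intercept", "age_center") if k not in data]
        if missing:
            raise CoefficientError(f"coefficient file missing required fields: {missing}")
        return cls(
            intercept=float(data["intercept"]),
            age_center=float(data["age_center"]),
            b_ej_noa_age=float(data.get("b_ej_noa_age", 0.0)),
            b_surg_noa_age=float(data.get("b_surg_noa_age", 0.0)),
            s_ej_noa=float(data.get("s_ej_noa", 0.0)),
            g_anat_andro=float(data.get("g_anat_andro", 0.0)),
            g_gen_anat=float(data.get("g_gen_anat", 0.0)),
            label=str(data.get("label", "")),
            platform_note=str(data.get("platform_note", "")),
            stderr=data.get("stderr"),
        )

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.to_dict(), handle, indent=2, sort_keys=True)
            handle.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "CoefficientSet":
        with open(path, encoding="utf-8") as handle:
            return cls.from_dict(json.load(handle))


def default_coefficients() -> CoefficientSet:
    """The packaged multicenter validation coefficient set."""
    text = resources.files("euplokit.data").joinpath("validation_model.json").read_text()
    return CoefficientSet.from_dict(json.loads(text))


@dataclass(frozen=True)
class PatientProfile:
    """Covariates required to evaluate the probability model."""

    female_age: float
    sperm_source: SpermSource = SpermSource.EJACULATE
    center: Center = Center.UNSPECIFIED

    def __post_init__(self) -> None:
        if not math.isfinite(self.female_age) or not (AGE_MIN <= self.female_age <= AGE_MAX):
            raise ProfileError(
                f"female_age must lie in [{AGE_MIN}, {AGE_MAX}] years, got {self.female_age}"
            )


def effect_codes(sperm_source: SpermSource, center: Center) -> tuple[int, int, int, int]:
    """Indicator-difference codes ``(d1, d2, e1, e2)`` for a profile.

    ``d1 = I(ejaculate) - I(testicular NOA)``,
    ``d2 = I(surgical non-NOA) - I(testicular NOA)``,
    ``e1 = I(Anatolia) - I(Androfert)``,
    ``e2 = I(GENERA) - I(Anatolia)``; an unspecified center zeroes both
    center codes.
    """
    d1 = (sperm_source is SpermSource.EJACULATE) - (sperm_source is SpermSource.TESTICULAR_NOA)
    d2 = (sperm_source is SpermSource.SURGICAL_NON_NOA) - (
        sperm_source is SpermSource.TESTICULAR_NOA
    )
    e1 = (center is Center.ANATOLIA) - (center is Center.ANDROFERT)
    e2 = (center is Center.GENERA) - (center is Center.ANATOLIA)
    return d1, d2, e1, e2


def linear_predictor(profile: PatientProfile, coefs: CoefficientSet) -> float:
    """Evaluate the linear predictor ``Y`` on the logit scale."""
    d1, d2, e1, e2 = effect_codes(profile.sperm_source, profile.center)
    age_dev = profile.female_age - coefs.age_center
    return (
        coefs.intercept
        + coefs.b_ej_noa_age * d1 * age_dev
        + coefs.b_surg_noa_age * d2 * age_dev
        + coefs.s_ej_noa * d1
        + coefs.g_anat_andro * e1
        + coefs.g_gen_anat * e2
    )


def euploidy_probability(y: float) -> float:
    """Inverse logit, ``p = 1 / (1 + exp(-Y))``."""
    if not math.isfinite(y):
        raise DomainError(f"linear predictor must be finite, got {y!r}")
    if y >= 0:
        return 1.0 / (1.0 + math.exp(-y))
    expy = math.exp(y)
    return expy / (1.0 + expy)


@dataclass(frozen=True)
class EuploidyPrediction:
    """Linear predictor and its probability for one profile."""

    y: float
    p: float

    @classmethod
    def from_profile(cls, profile: PatientProfile, coefs: CoefficientSet) -> "EuploidyPrediction":
        y = linear_predictor(profile, coefs)
        return cls(y=y, p=euploidy_probability(y))


@dataclass(frozen=True)
class MIIEstimate:
    """Minimum-oocyte answer for one ``(p, pi)`` query.

    ``achieved_success = 1 - (1-p)**mii_min`` is the actual success
    probability at the returned count; ``risk = 1 - pi`` is the
    user-accepted failure probability.
    """

    p: float
    pi: float
    mii_min: int
    risk: float
    achieved_success: float


def _success_probability(p: float, n: int) -> float:
    # 1 - (1-p)^n via expm1/log1p for accuracy at small p
    return -math.expm1(n * math.log1p(-p))


def mii_min(p: float, pi: float) -> MIIEstimate:
    """Smallest integer ``N >= 0`` with ``1 - (1-p)**N >= pi``.

    Computed by integer search seeded from the log-ratio bound
    ``log(1-pi)/log(1-p)`` rather than a raw ceiling, so near-integer
    ratios do not flip the answer by one through rounding error.
    """
    if not (0.0 < p < 1.0):
        raise DomainError(f"per-oocyte probability must lie strictly in (0, 1), got {p}")
    if not (0.0 < pi < 1.0):
        raise DomainError(f"success probability must lie strictly in (0, 1), got {pi}")

    bound = math.log1p(-pi) / math.log1p(-p)
    if bound > _MAX_MII:
        raise DomainError(
            f"target success {pi} is unreachable at p={p}: "
            f"required count exceeds {_MAX_MII:.0e}"
        )
    n = max(0, int(math.floor(bound)) - 1)
    threshold = pi * (1.0 - _BOUNDARY_RTOL)
    while _success_probability(p, n) < threshold:
        n += 1
    return MIIEstimate(
        p=p,
        pi=pi,
        mii_min=n,
        risk=1.0 - pi,
        achieved_success=_success_probability(p, n),
    )


def predict(profile: PatientProfile, pi: float, coefs: CoefficientSet) -> MIIEstimate:
    """Full per-patient query: profile -> p -> minimum MII count."""
    return mii_min(euploidy_probability(linear_predictor(profile, coefs)), pi)


def probability_interval(
    profile: PatientProfile, coefs: CoefficientSet, level: float = 0.95
) -> tuple[float, float]:
    """Approximate confidence interval for ``p``.

    Normal approximation on the logit scale from the stored per-coefficient
    standard errors; coefficient covariances are not available, so the
    interval treats the terms as independent and is approximate.
    """
    if coefs.stderr is None:
        raise CoefficientError("coefficient set carries no standard errors")
    if not (0.0 < level < 1.0):
        raise DomainError(f"confidence level must lie in (0, 1), got {level}")
    from scipy.stats import norm

    d1, d2, e1, e2 = effect_codes(profile.sperm_source, profile.center)
    age_dev = profile.female_age - coefs.age_center
    design = {
        "intercept": 1.0,
        "b_ej_noa_age": d1 * age_dev,
        "b_surg_noa_age": d2 * age_dev,
        "s_ej_noa": d1,
        "g_anat_andro": e1,
        "g_gen_anat": e2,
    }
    var = 0.0
    for name, x in design.items():
        se = coefs.stderr.get(name)
        if se is not None and x != 0.0:
            var += (x * se) ** 2
    y = linear_predictor(profile, coefs)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(var)
    return euploidy_probability(y - half), euploidy_probability(y + half)
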