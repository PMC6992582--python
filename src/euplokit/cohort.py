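"""Synthetic CRF-style cohort generator.

Generates per-couple records with the statistical structure the downstream
analysis assumes: ages from a truncated normal, negative-binomial MII
counts, and a binomial cascade MII -> 2PN -> blastocyst -> euploid whose
thinning rates are chosen so that, marginally, the euploid count given the
MII count is Binomial(N, p) with p taken from a ground-truth coefficient
set.  Mixing heterogeneous ages then yields the overdispersed
(Gamma-Poisson-like) marginal euploid-count distribution.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from scipy.stats import truncnorm

from .calculator import (
    Center,
    CoefficientSet,
    PatientProfile,
    SpermSource,
    default_coefficients,
    euploidy_probability,
    linear_predictor,
)
from .errors import CohortSpecError, SchemaError

__all__ = [
    "AgeModel",
    "StageRates",
    "CohortSpec",
    "PatientRecord",
    "generate_cohort",
    "summarize_cohort",
    "write_crf",
    "read_crf",
    "CRF_COLUMNS",
]

#: Documented CRF schema, version 1.  Required columns, in order.
CRF_COLUMNS = (
    "patient_id",
    "female_age",
    "sperm_source",
    "center",
    "n_mii",
    "n_2pn",
    "n_blast",
    "n_euploid",
)


@dataclass(frozen=True)
class AgeModel:
    """Truncated-normal female-age distribution (years)."""

    mean: float = 39.4
    sd: float = 3.4
    lower: float = 25.0
    upper: float = 46.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise CohortSpecError(f"age sd must be positive, got {self.sd}")
        if not self.lower < self.upper:
            raise CohortSpecError("age bounds must satisfy lower < upper")


@dataclass(frozen=True)
class StageRates:
    """Per-center fertilization and blastulation rates, each in (0, 1]."""

    fertilization: float = 0.80
    blastulation: float = 0.70

    def __post_init__(self) -> None:
        for name in ("fertilization", "blastulation"):
            rate = getattr(self, name)
            if not (0.0 < rate <= 1.0):
                raise CohortSpecError(f"{name} rate must lie in (0, 1], got {rate}")


def _default_sperm_mix() -> dict[SpermSource, float]:
    return {
        SpermSource.EJACULATE: 0.927,
        SpermSource.SURGICAL_NON_NOA: 0.037,
        SpermSource.TESTICULAR_NOA: 0.036,
    }


def _default_center_mix() -> dict[Center, float]:
    # patient counts 620 / 257 / 587 across the three centers
    total = 620 + 257 + 587
    return {
        Center.ANATOLIA: 620 / total,
        Center.ANDROFERT: 257 / total,
        Center.GENERA: 587 / total,
    }


def _default_stage_rates() -> dict[Center, StageRates]:
    return {center: StageRates() for center in Center}


@dataclass(frozen=True)
class CohortSpec:
    """All simulator knobs; fully determines a cohort together with the seed.

    ``mii_age_slope`` is an optional log-linear trend of the mean MII count
    in age (per year, applied to ``age - age_model.mean``); it defaults to
    zero because the joint law of age and oocyte yield is not constrained
    by the marginal summaries the defaults emulate.
    """

    n_patients: int = 1464
    age_model: AgeModel = field(default_factory=AgeModel)
    sperm_mix: Mapping[SpermSource, float] = field(default_factory=_default_sperm_mix)
    center_mix: Mapping[Center, float] = field(default_factory=_default_center_mix)
    mii_mean: float = 6.7
    mii_dispersion: float = 3.0
    mii_age_slope: float = 0.0
    stage_rates: Mapping[Center, StageRates] = field(default_factory=_default_stage_rates)
    truth: CoefficientSet = field(default_factory=default_coefficients)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise CohortSpecError(f"n_patients must be positive, got {self.n_patients}")
        if self.mii_mean <= 0 or self.mii_dispersion <= 0:
            raise CohortSpecError("MII negative-binomial mean and dispersion must be positive")
        for label, mix in (("sperm_mix", self.sperm_mix), ("center_mix", self.center_mix)):
            probs = list(mix.values())
            if any(w < 0 for w in probs) or not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
                raise CohortSpecError(f"{label} must be a probability vector summing to 1")
        for center in self.center_mix:
            if self.center_mix[center] > 0 and center not in self.stage_rates:
                raise CohortSpecError(f"no stage rates configured for center {center.value}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_patients": self.n_patients,
            "age_model": {
                "mean": self.age_model.mean,
                "sd": self.age_model.sd,
                "lower": self.age_model.lower,
                "upper": self.age_model.upper,
            },
            "sperm_mix": {k.value: v for k, v in self.sperm_mix.items()},
            "center_mix": {k.value: v for k, v in self.center_mix.items()},
            "mii_mean": self.mii_mean,
            "mii_dispersion": self.mii_dispersion,
            "mii_age_slope": self.mii_age_slope,
            "stage_rates": {
                k.value: {"fertilization": v.fertilization, "blastulation": v.blastulation}
                for k, v in self.stage_rates.items()
            },
            "truth": self.truth.to_dict(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "CohortSpec":
        kwargs: dict[str, Any] = {}
        if "n_patients" in data:
            kwargs["n_patients"] = int(data["n_patients"])
        if "age_model" in data:
            kwargs["age_model"] = AgeModel(**data["age_model"])
        if "sperm_mix" in data:
            kwargs["sperm_mix"] = {SpermSource(k): float(v) for k, v in data["sperm_mix"].items()}
        if "center_mix" in data:
            kwargs["center_mix"] = {Center(k): float(v) for k, v in data["center_mix"].items()}
        for key in ("mii_mean", "mii_dispersion", "mii_age_slope"):
            if key in data:
                kwargs[key] = float(data[key])
        if "stage_rates" in data:
            kwargs["stage_rates"] = {
                Center(k): StageRates(**v) for k, v in data["stage_rates"].items()
            }
        if "truth" in data:
            kwargs["truth"] = CoefficientSet.from_dict(data["truth"])
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        return cls(**kwargs)

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.to_dict(), handle, indent=2, sort_keys=True)
            handle.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "CohortSpec":
        with open(path, encoding="utf-8") as handle:
            return cls.from_dict(json.load(handle))

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass(frozen=True)
class PatientRecord:
    """One CRF row: covariates plus the observed count cascade."""

    patient_id: str
    female_age: float
    sperm_source: SpermSource
    center: Center
    n_mii: int
    n_2pn: int
    n_blast: int
    n_euploid: int

    def __post_init__(self) -> None:
        counts = (self.n_euploid, self.n_blast, self.n_2pn, self.n_mii)
        if any(c < 0 for c in counts):
            raise SchemaError(f"record {self.patient_id}: negative count")
        if not (self.n_euploid <= self.n_blast <= self.n_2pn <= self.n_mii):
            raise SchemaError(
                f"record {self.patient_id}: counts must satisfy "
                "euploid <= blastocysts <= 2PN <= MII"
            )

    @property
    def profile(self) -> PatientProfile:
        return PatientProfile(self.female_age, self.sperm_source, self.center)


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a cohort; byte-identical for identical ``spec`` (incl. seed).

    The euploid count is produced by hierarchical binomial thinning
    ``Bin(N, f) -> Bin(., b) -> Bin(., p/(f*b))`` so that marginally
    ``m | N ~ Binomial(N, p)`` while the intermediate 2PN and blastocyst
    counts remain jointly consistent.  Raises when any patient's implied
    per-blastocyst euploidy ``p/(f*b)`` exceeds 1.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    am = spec.age_model
    a, b = (am.lower - am.mean) / am.sd, (am.upper - am.mean) / am.sd
    ages = truncnorm.rvs(a, b, loc=am.mean, scale=am.sd, size=n, random_state=rng)

    sperm_levels = list(spec.sperm_mix)
    sperm = rng.choice(len(sperm_levels), size=n, p=[spec.sperm_mix[s] for s in sperm_levels])
    center_levels = list(spec.center_mix)
    centers = rng.choice(len(center_levels), size=n, p=[spec.center_mix[c] for c in center_levels])

    k = spec.mii_dispersion
    mu = spec.mii_mean * np.exp(spec.mii_age_slope * (ages - am.mean))
    n_mii = rng.negative_binomial(k, k / (k + mu))

    records: list[PatientRecord] = []
    for i in range(n):
        source = sperm_levels[int(sperm[i])]
        center = center_levels[int(centers[i])]
        profile = PatientProfile(float(ages[i]), source, center)
        p = euploidy_probability(linear_predictor(profile, spec.truth))
        rates = spec.stage_rates[center]
        fb = rates.fertilization * rates.blastulation
        e = p / fb
        if e > 1.0:
            raise CohortSpecError(
                f"stage rates inconsistent with truth model: patient {i} has "
                f"p={p:.4f} > fertilization*blastulation={fb:.4f} "
                f"for center {center.value}"
            )
        n2pn = int(rng.binomial(int(n_mii[i]), rates.fertilization))
        nblast = int(rng.binomial(n2pn, rates.blastulation))
        m = int(rng.binomial(nblast, e))
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:05d}",
                female_age=float(ages[i]),
                sperm_source=source,
                center=center,
                n_mii=int(n_mii[i]),
                n_2pn=n2pn,
                n_blast=nblast,
                n_euploid=m,
            )
        )
    return records


def _quantiles(values: np.ndarray) -> dict[str, float]:
    qs = np.quantile(values, [0.025, 0.25, 0.5, 0.75, 0.975])
    return {
        "mean": float(np.mean(values)),
        "q2.5": float(qs[0]),
        "q25": float(qs[1]),
        "median": float(qs[2]),
        "q75": float(qs[3]),
        "q97.5": float(qs[4]),
    }


def summarize_cohort(records: Sequence[PatientRecord]) -> dict[str, Any]:
    """Demographics/treatment summary table as a JSON-serializable dict."""
    if not records:
        raise SchemaError("cannot summarize an empty cohort")
    ages = np.array([r.female_age for r in records])
    n_mii = np.array([r.n_mii for r in records])
    n_2pn = np.array([r.n_2pn for r in records])
    n_blast = np.array([r.n_blast for r in records])
    m = np.array([r.n_euploid for r in records])
    total_blast = int(n_blast.sum())
    return {
        "n_patients": len(records),
        "female_age": _quantiles(ages),
        "n_mii": _quantiles(n_mii.astype(float)),
        "n_2pn": _quantiles(n_2pn.astype(float)),
        "n_blast": _quantiles(n_blast.astype(float)),
        "n_euploid": _quantiles(m.astype(float)),
        "sperm_source": {
            s.value: int(sum(r.sperm_source is s for r in records)) for s in SpermSource
        },
        "center": {c.value: int(sum(r.center is c for r in records)) for c in Center},
        "total_mii": int(n_mii.sum()),
        "total_blastocysts": total_blast,
        "euploid_per_blastocyst_pct": (
            float(100.0 * m.sum() / total_blast) if total_blast else None
        ),
        "fertilization_rate": float(n_2pn.sum() / n_mii.sum()) if n_mii.sum() else None,
        "blastulation_rate": float(n_blast.sum() / n_2pn.sum()) if n_2pn.sum() else None,
    }


def write_crf(
    records: Sequence[PatientRecord], path: str, metadata: Mapping[str, Any] | None = None
) -> None:
    """Write a cohort as CRF CSV (schema v1), with provenance comment lines.

    Floats are written with shortest round-tripping repr, so a
    write/read cycle is lossless.
    """
    with open(path, "w", encoding="utf-8", newline="") as handle:
        handle.write("# euplokit-crf v1\n")
        if metadata:
            for key in sorted(metadata):
                handle.write(f"# {key}={metadata[key]}\n")
        writer = csv.writer(handle)
        writer.writerow(CRF_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    repr(r.female_age),
                    r.sperm_source.value,
                    r.center.value,
                    r.n_mii,
                    r.n_2pn,
                    r.n_blast,
                    r.n_euploid,
                ]
            )


def read_crf(path: str) -> list[PatientRecord]:
    """Read and validate a CRF CSV; unknown extra columns are tolerated.

    Malformed rows (negative counts, violated count ordering, bad
    categories) are collected and reported together with their row
    indices (0-based, counting data rows).
    """
    with open(path, encoding="utf-8", newline="") as handle:
        lines = [line for line in handle if not line.startswith("#")]
    reader = csv.DictReader(lines)
    if reader.fieldnames is None:
        raise SchemaError(f"{path}: empty CRF file")
    missing = [c for c in CRF_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    records: list[PatientRecord] = []
    bad: list[tuple[int, str]] = []
    for idx, row in enumerate(reader):
        try:
            records.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    female_age=float(row["female_age"]),
                    sperm_source=SpermSource(row["sperm_source"]),
                    center=Center(row["center"]),
                    n_mii=int(row["n_mii"]),
                    n_2pn=int(row["n_2pn"]),
                    n_blast=int(row["n_blast"]),
                    n_euploid=int(row["n_euploid"]),
                )
            )
        except (SchemaError, ValueError, KeyError) as exc:
            bad.append((idx, str(exc)))
    if bad:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad[:10])
        raise SchemaError(
            f"{path}: {len(bad)} invalid row(s): {detail}", rows=[i for i, _ in bad]
        )
    return records
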