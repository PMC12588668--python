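"""Patient data model and synthetic cohort generation.

A cohort is a list of :class:`Patient` records carrying the demographics and
laboratory values that every renal-function estimator consumes.  The synthetic
generator emulates the covariate structure of a small prospective carboplatin
PK study stratified by BMI category (<25.0, 25.0–29.9, ≥30.0 kg/m²), and
attaches a latent "true" carboplatin clearance to each patient so the whole
dosing → sampling → estimation → evaluation pipeline is testable without any
external data.

The latent truth is built on the Calvert relation CL = GFR + 25 mL/min: a
configurable "truth" renal formula defines each patient's latent creatinine
clearance, and the true carboplatin clearance is (CrCL_truth + 25)·exp(η) with
log-normal inter-individual variability η ~ N(0, ω²).  The 24-h urine
creatinine excretion is back-computed from the latent CrCL so that a 24-h
creatinine-clearance estimator applied to the emitted record recovers the
latent value up to the configured measurement noise.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Sex",
    "Stratum",
    "Patient",
    "LatentTruth",
    "StratumSpec",
    "CohortSpec",
    "generate_cohort",
    "read_cohort",
    "write_cohort",
    "write_truths",
    "read_truths",
    "compute_bmi",
]


class Sex(str, enum.Enum):
    MALE = "M"
    FEMALE = "F"


class Stratum(str, enum.Enum):
    """BMI category. Lower bound inclusive, upper bound exclusive."""

    NORMAL = "<25.0"
    OVERWEIGHT = "25.0-29.9"
    OBESE = ">=30.0"

    @property
    def bmi_bounds(self) -> tuple[float, float]:
        return {
            Stratum.NORMAL: (0.0, 25.0),
            Stratum.OVERWEIGHT: (25.0, 30.0),
            Stratum.OBESE: (30.0, math.inf),
        }[self]

    def contains(self, bmi: float) -> bool:
        lo, hi = self.bmi_bounds
        return lo <= bmi < hi

    @classmethod
    def classify(cls, bmi: float) -> "Stratum":
        for s in cls:
            if s.contains(bmi):
                return s
        raise ValueError(f"BMI {bmi} outside all strata")


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index in kg/m²."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return weight_kg / (height_cm / 100.0) ** 2


ALLOWED_TARGET_AUCS = (4.0, 5.0, 6.0)


@dataclass(frozen=True)
class Patient:
    """One subject: covariate source for every dosing formula.

    Units: age years, weight kg (absolute body weight), height cm, serum
    creatinine µmol/L, cystatin C mg/L, 24-h urine creatinine mmol/24 h,
    target AUC mg·min/mL.
    """

    id: str
    sex: Sex
    age: int
    weight_kg: float
    height_cm: float
    scr_umol_l: float
    target_auc: float
    cysc_mg_l: Optional[float] = None
    ucr_mmol_24h: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        if self.age < 18:
            raise ValueError(f"patient {self.id}: age must be >= 18")
        for name in ("weight_kg", "height_cm", "scr_umol_l"):
            if getattr(self, name) <= 0:
                raise ValueError(f"patient {self.id}: {name} must be positive")
        if self.target_auc not in ALLOWED_TARGET_AUCS:
            raise ValueError(
                f"patient {self.id}: target_auc {self.target_auc} not in "
                f"{ALLOWED_TARGET_AUCS}"
            )
        for name in ("cysc_mg_l", "ucr_mmol_24h"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"patient {self.id}: {name} must be positive")

    @property
    def bmi(self) -> float:
        return compute_bmi(self.weight_kg, self.height_cm)

    @property
    def stratum(self) -> Stratum:
        return Stratum.classify(self.bmi)


@dataclass(frozen=True)
class LatentTruth:
    """Simulation ground truth for one patient."""

    true_cl_ml_min: float
    eta_cl: float
    true_crcl_ml_min: float

    def __post_init__(self) -> None:
        if self.true_cl_ml_min <= 0 or self.true_crcl_ml_min <= 0:
            raise ValueError("latent clearances must be positive")


@dataclass(frozen=True)
class StratumSpec:
    """Covariate ranges for one BMI stratum (sampled uniformly)."""

    n: int
    age_range: tuple[int, int]
    weight_range: tuple[float, float]
    height_range: tuple[float, float]
    scr_range: tuple[float, float]
    cysc_range: tuple[float, float]
    p_male: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("stratum sample size must be >= 0")
        for name in ("age_range", "weight_range", "height_range", "scr_range", "cysc_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} bounds out of order: ({lo}, {hi})")
        if not 0.0 <= self.p_male <= 1.0:
            raise ValueError("p_male must be in [0, 1]")


def _default_strata() -> dict[Stratum, StratumSpec]:
    # Ranges follow the observed per-stratum covariate ranges of the study
    # cohort; sex probabilities follow the observed M/F counts (6/1, 1/4, 3/3).
    return {
        Stratum.NORMAL: StratumSpec(
            n=7, age_range=(50, 78), weight_range=(48.0, 80.0),
            height_range=(171.0, 185.0), scr_range=(49.0, 95.0),
            cysc_range=(0.8, 1.6), p_male=6 / 7,
        ),
        Stratum.OVERWEIGHT: StratumSpec(
            n=5, age_range=(54, 77), weight_range=(72.0, 81.0),
            height_range=(166.0, 173.0), scr_range=(67.0, 130.0),
            cysc_range=(0.8, 1.9), p_male=1 / 5,
        ),
        Stratum.OBESE: StratumSpec(
            n=6, age_range=(56, 78), weight_range=(87.0, 115.0),
            height_range=(160.0, 180.0), scr_range=(57.0, 114.0),
            cysc_range=(0.8, 1.5), p_male=3 / 6,
        ),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort.

    ``truth_method`` names the renal formula whose CrCL defines each
    patient's latent clearance; ``omega_cl`` is the log-scale SD of the
    inter-individual deviation on carboplatin clearance and ``ucr_noise_cv``
    the multiplicative (log-normal) noise on the back-computed 24-h urine
    creatinine.  ``seed`` makes generation bit-reproducible: each patient
    draws from a substream keyed by (seed, patient index), so enlarging a
    stratum never reshuffles earlier patients.
    """

    strata: dict[Stratum, StratumSpec] = field(default_factory=_default_strata)
    omega_cl: float = 0.2
    ucr_noise_cv: float = 0.10
    truth_method: str = "aCG"
    target_auc_choices: tuple[float, ...] = (5.0, 6.0)
    target_auc_probs: tuple[float, ...] = (0.2, 0.8)
    p_missing_cysc: float = 0.0
    p_missing_ucr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega_cl < 0 or self.ucr_noise_cv < 0:
            raise ValueError("variability parameters must be >= 0")
        if len(self.target_auc_choices) != len(self.target_auc_probs):
            raise ValueError("target AUC choices and probabilities differ in length")
        if abs(sum(self.target_auc_probs) - 1.0) > 1e-9:
            raise ValueError("target AUC probabilities must sum to 1")
        for p in (self.p_missing_cysc, self.p_missing_ucr):
            if not 0.0 <= p <= 1.0:
                raise ValueError("missingness probabilities must be in [0, 1]")


_MAX_RESAMPLE = 10_000


def generate_cohort(
    spec: CohortSpec,
    constants=None,
    coefficients=None,
) -> list[tuple[Patient, LatentTruth]]:
    """Generate a synthetic cohort with latent truth.

    Covariates are drawn uniformly within the configured per-stratum ranges;
    (weight, height) pairs falling outside the stratum's BMI band are
    resampled so stratum purity is exact.  The latent creatinine clearance is
    the ``truth_method`` formula evaluated on the generated covariates, the
    true carboplatin clearance is (CrCL + calvert_offset)·exp(η), and the
    24-h urine creatinine is back-computed as CrCL·Scr·1440/10⁶ mmol/24 h
    with multiplicative log-normal noise.
    """
    from . import renal  # deferred: renal imports Patient from this module

    if constants is None:
        constants = renal.DosingConstants()
    if coefficients is None:
        coefficients = renal.load_coefficients()
    if spec.truth_method not in renal.METHODS:
        raise ValueError(f"unknown truth method {spec.truth_method!r}")
    if spec.truth_method == "crcl_24h":
        raise ValueError(
            "crcl_24h cannot define the latent truth: the urine creatinine "
            "is itself back-computed from the latent CrCL"
        )

    out: list[tuple[Patient, LatentTruth]] = []
    index = 0
    for stratum in Stratum:
        sspec = spec.strata.get(stratum)
        if sspec is None or sspec.n == 0:
            continue
        lo_bmi, hi_bmi = stratum.bmi_bounds
        for _ in range(sspec.n):
            rng = np.random.default_rng([spec.seed, index])
            sex = Sex.MALE if rng.random() < sspec.p_male else Sex.FEMALE
            age = int(rng.integers(sspec.age_range[0], sspec.age_range[1] + 1))
            for attempt in range(_MAX_RESAMPLE):
                weight = rng.uniform(*sspec.weight_range)
                height = rng.uniform(*sspec.height_range)
                if stratum.contains(compute_bmi(weight, height)):
                    break
            else:
                raise ValueError(
                    f"stratum {stratum.value}: weight/height ranges cannot "
                    f"produce BMI in [{lo_bmi}, {hi_bmi})"
                )
            scr = rng.uniform(*sspec.scr_range)
            cysc = rng.uniform(*sspec.cysc_range)
            target = float(
                rng.choice(np.asarray(spec.target_auc_choices), p=spec.target_auc_probs)
            )
            eta = float(rng.normal(0.0, spec.omega_cl)) if spec.omega_cl > 0 else 0.0

            patient = Patient(
                id=f"SIM{index + 1:03d}",
                sex=sex,
                age=age,
                weight_kg=weight,
                height_cm=height,
                scr_umol_l=scr,
                cysc_mg_l=cysc,
                target_auc=target,
            )
            truth_est = renal.METHODS[spec.truth_method](patient, constants, coefficients)
            true_crcl = truth_est.crcl
            true_cl = (true_crcl + constants.calvert_offset) * math.exp(eta)

            ucr = true_crcl * scr * 1440.0 / 1e6  # mmol per 24 h
            if spec.ucr_noise_cv > 0:
                ucr *= math.exp(rng.normal(0.0, spec.ucr_noise_cv))

            if spec.p_missing_cysc > 0 and rng.random() < spec.p_missing_cysc:
                patient = replace(patient, cysc_mg_l=None)
            if not (spec.p_missing_ucr > 0 and rng.random() < spec.p_missing_ucr):
                patient = replace(patient, ucr_mmol_24h=ucr)

            out.append(
                (patient, LatentTruth(true_cl_ml_min=true_cl, eta_cl=eta,
                                      true_crcl_ml_min=true_crcl))
            )
            index += 1
    return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "id", "sex", "age", "weight_kg", "height_cm", "scr_umol_l",
    "cysc_mg_l", "ucr_mmol_24h", "target_auc", "stratum",
]
TRUTH_COLUMNS = ["id", "true_cl_ml_min", "eta_cl", "true_crcl_ml_min"]


def _fmt(x: Optional[float]) -> str:
    if x is None:
        return ""
    return format(float(x), ".17g")


def write_cohort(cohort: Sequence[Patient], path) -> None:
    """Write a cohort CSV (UTF-8, dot decimals, blank = missing)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(COHORT_COLUMNS)
        for p in cohort:
            w.writerow([
                p.id, p.sex.value, str(p.age), _fmt(p.weight_kg),
                _fmt(p.height_cm), _fmt(p.scr_umol_l), _fmt(p.cysc_mg_l),
                _fmt(p.ucr_mmol_24h), _fmt(p.target_auc), p.stratum.value,
            ])


def read_cohort(path, strict: bool = True) -> list[Patient]:
    """Read a cohort CSV; numbers preserved to full stored precision."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in COHORT_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"cohort file missing mandatory column(s): {missing}")
        unknown = [c for c in header if c not in COHORT_COLUMNS]
        if unknown and strict:
            raise ValueError(f"cohort file has unknown column(s): {unknown}")
        patients = []
        for i, row in enumerate(reader, start=2):
            try:
                sex = Sex(row["sex"])
            except ValueError:
                raise ValueError(
                    f"line {i}: sex must be 'M' or 'F', got {row['sex']!r}"
                ) from None
            try:
                p = Patient(
                    id=row["id"],
                    sex=sex,
                    age=int(row["age"]),
                    weight_kg=float(row["weight_kg"]),
                    height_cm=float(row["height_cm"]),
                    scr_umol_l=float(row["scr_umol_l"]),
                    cysc_mg_l=float(row["cysc_mg_l"]) if row["cysc_mg_l"] else None,
                    ucr_mmol_24h=float(row["ucr_mmol_24h"]) if row["ucr_mmol_24h"] else None,
                    target_auc=float(row["target_auc"]),
                )
            except ValueError as exc:
                raise ValueError(f"line {i}: {exc}") from None
            declared = Stratum(row["stratum"])
            if p.stratum is not declared:
                raise ValueError(
                    f"line {i}: declared stratum {declared.value} inconsistent "
                    f"with BMI {p.bmi:.2f}"
                )
            patients.append(p)
    return patients


def write_truths(cohort: Sequence[tuple[Patient, LatentTruth]], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(TRUTH_COLUMNS)
        for p, t in cohort:
            w.writerow([p.id, _fmt(t.true_cl_ml_min), _fmt(t.eta_cl),
                        _fmt(t.true_crcl_ml_min)])


def read_truths(path) -> dict[str, LatentTruth]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in TRUTH_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"truth file missing column(s): {missing}")
        return {
            row["id"]: LatentTruth(
                true_cl_ml_min=float(row["true_cl_ml_min"]),
                eta_cl=float(row["eta_cl"]),
                true_crcl_ml_min=float(row["true_crcl_ml_min"]),
            )
            for row in reader
        }
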