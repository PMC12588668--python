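"""Renal-function and carboplatin-clearance estimators.

Every estimator compared in the dosing study is exposed through a uniform
registry keyed by method name and returns a :class:`RenalEstimate` whose
``crcl`` slot is the GFR surrogate entering the Calvert formula
(dose = target AUC × (CrCL + 25)).  Methods that predict carboplatin
clearance *directly* (the cystatin-C covariate model, the Chatelut-type
Bénézet model, flat dosing) store clearance − calvert_offset in that slot and
set ``direct_clearance`` so downstream Calvert reconstruction (crcl + 25)
returns the formula's clearance exactly and the offset is never added twice.

The adjusted Cockcroft–Gault (aCG) dosing algorithm is: use adjusted ideal
body weight instead of absolute body weight when BMI ≥ 25 kg/m², floor serum
creatinine at 60 µmol/L, and cap the estimated creatinine clearance at
125 mL/min.
"""

from __future__ import annotations

import hashlib
import logging
import math
import tomllib
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Literal, Optional

from .cohort import Patient, Sex, compute_bmi

__all__ = [
    "DosingConstants",
    "RenalEstimate",
    "FormulaCoefficients",
    "MissingCovariateError",
    "load_coefficients",
    "ibw",
    "aibw",
    "bsa_dubois",
    "cockcroft_gault",
    "adjusted_cg",
    "conventional_cg",
    "benezet_crcl",
    "schmitt_clearance",
    "ckdepi",
    "crcl_24h",
    "crcl_24h_estimate",
    "flat_clearance",
    "METHODS",
    "evaluate_methods",
    "compute_bmi",
]

log = logging.getLogger(__name__)

WeightDescriptor = Literal["ABW", "AIBW", "IBW", "none"]


class MissingCovariateError(ValueError):
    """A method requires a covariate the patient record does not carry."""

    def __init__(self, method: str, covariate: str, patient_id: str = ""):
        self.method = method
        self.covariate = covariate
        self.patient_id = patient_id
        super().__init__(
            f"method {method!r} requires {covariate} "
            f"(patient {patient_id or '?'}): excluded"
        )


@dataclass(frozen=True)
class DosingConstants:
    """Clinical constants of the dosing algorithm.

    calvert_offset — non-renal clearance term of the Calvert formula, mL/min;
    crcl_cap — upper cap on estimated CrCL, mL/min; scr_floor — lower floor
    on serum creatinine, µmol/L; bmi_threshold — BMI at and above which AIBW
    replaces ABW, kg/m²; flat_population_cl — mean population carboplatin
    clearance used by flat dosing, mL/min; aibw_factor — fraction of the
    weight excess over IBW added back.
    """

    calvert_offset: float = 25.0
    crcl_cap: float = 125.0
    scr_floor: float = 60.0
    bmi_threshold: float = 25.0
    flat_population_cl: float = 112.4
    aibw_factor: float = 0.4

    def __post_init__(self) -> None:
        for name in ("calvert_offset", "crcl_cap", "scr_floor",
                     "bmi_threshold", "flat_population_cl", "aibw_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class RenalEstimate:
    """One estimator's GFR surrogate, with provenance flags."""

    method: str
    crcl: float                      # mL/min, the value entering Calvert
    raw_crcl: float                  # pre-cap value
    weight_used: Optional[float] = None
    weight_descriptor: WeightDescriptor = "none"
    scr_floored: bool = False
    crcl_capped: bool = False
    direct_clearance: bool = False   # crcl slot holds clearance - offset

    def __post_init__(self) -> None:
        if self.crcl <= 0:
            raise ValueError(f"{self.method}: crcl must be positive")
        if self.crcl > self.raw_crcl + 1e-12:
            raise ValueError(f"{self.method}: crcl exceeds raw_crcl")

    def clearance(self, constants: DosingConstants) -> float:
        """Carboplatin clearance implied by the Calvert relation, mL/min."""
        return self.crcl + constants.calvert_offset


class FormulaCoefficients:
    """Named coefficient sets for every registered formula.

    Loaded from a TOML file; loading fails loudly if any registered formula's
    table or key is missing. The file's SHA-256 is logged for provenance.
    """

    REQUIRED: dict[str, tuple[str, ...]] = {
        "cockcroft_gault": ("f_male", "f_female"),
        "devine_ibw": ("base_male_kg", "base_female_kg", "kg_per_inch",
                       "reference_height_cm", "cm_per_inch"),
        "dubois_bsa": ("coefficient", "weight_exponent", "height_exponent"),
        "chatelut_benezet": ("theta_weight", "theta_renal", "age_slope",
                             "female_factor"),
        "schmitt": ("typical_cl_ml_min", "cysc_ref_mg_l", "cysc_exp",
                    "weight_ref_kg", "weight_exp", "age_ref_yr", "age_exp",
                    "scr_ref_umol_l", "scr_exp", "female_factor"),
        "ckdepi_creatinine": ("intercept", "kappa_female", "kappa_male",
                              "alpha_female", "alpha_male", "beta",
                              "age_base", "female_factor"),
        "ckdepi_creatinine_cystatin": ("intercept", "kappa_female",
                                       "kappa_male", "alpha_female",
                                       "alpha_male", "beta", "cys_kappa",
                                       "cys_alpha", "cys_beta", "age_base",
                                       "female_factor"),
    }

    def __init__(self, tables: dict[str, dict[str, float]]):
        for table, keys in self.REQUIRED.items():
            if table not in tables:
                raise ValueError(f"coefficient file missing table [{table}]")
            for k in keys:
                if k not in tables[table]:
                    raise ValueError(f"coefficient table [{table}] missing key {k!r}")
        self._tables = tables

    def __getitem__(self, table: str) -> dict[str, float]:
        return self._tables[table]


def load_coefficients(path=None) -> FormulaCoefficients:
    """Load formula coefficients from ``path`` or the packaged defaults."""
    if path is None:
        raw = resources.files("carbopk").joinpath("data/coefficients.toml").read_bytes()
    else:
        with open(path, "rb") as fh:
            raw = fh.read()
    log.info("formula coefficients loaded, sha256=%s", hashlib.sha256(raw).hexdigest())
    return FormulaCoefficients(tomllib.loads(raw.decode("utf-8")))


_DEFAULT_COEFFS: Optional[FormulaCoefficients] = None


def _default_coeffs() -> FormulaCoefficients:
    global _DEFAULT_COEFFS
    if _DEFAULT_COEFFS is None:
        _DEFAULT_COEFFS = load_coefficients()
    return _DEFAULT_COEFFS


# ---------------------------------------------------------------------------
# Weight descriptors and BSA
# ---------------------------------------------------------------------------

def ibw(sex: Sex, height_cm: float, coefficients: Optional[FormulaCoefficients] = None) -> float:
    """Devine ideal body weight, kg. Heights below the 60-inch reference
    extrapolate linearly (may go below the base weight)."""
    if height_cm <= 0:
        raise ValueError("height must be positive")
    c = (coefficients or _default_coeffs())["devine_ibw"]
    base = c["base_male_kg"] if Sex(sex) is Sex.MALE else c["base_female_kg"]
    inches_over = (height_cm - c["reference_height_cm"]) / c["cm_per_inch"]
    return base + c["kg_per_inch"] * inches_over


def aibw(
    sex: Sex,
    height_cm: float,
    weight_kg: float,
    constants: Optional[DosingConstants] = None,
    coefficients: Optional[FormulaCoefficients] = None,
) -> float:
    """Adjusted ideal body weight: IBW + factor × (ABW − IBW), kg."""
    constants = constants or DosingConstants()
    w_ideal = ibw(sex, height_cm, coefficients)
    return w_ideal + constants.aibw_factor * (weight_kg - w_ideal)


def bsa_dubois(
    weight_kg: float, height_cm: float,
    coefficients: Optional[FormulaCoefficients] = None,
) -> float:
    """Du Bois body surface area, m²."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    c = (coefficients or _default_coeffs())["dubois_bsa"]
    return c["coefficient"] * weight_kg ** c["weight_exponent"] * height_cm ** c["height_exponent"]


# ---------------------------------------------------------------------------
# Cockcroft–Gault family
# ---------------------------------------------------------------------------

def cockcroft_gault(
    weight_used_kg: float,
    age: float,
    sex: Sex,
    scr_umol_l: float,
    coefficients: Optional[FormulaCoefficients] = None,
) -> float:
    """Cockcroft–Gault CrCL (mL/min), µmol/L serum-creatinine dialect:
    (140 − age) × weight × F_sex / Scr with F_male 1.23, F_female 1.04."""
    if scr_umol_l <= 0:
        raise ValueError("serum creatinine must be positive")
    if age >= 140:
        raise ValueError("age must be below 140 years")
    c = (coefficients or _default_coeffs())["cockcroft_gault"]
    f = c["f_male"] if Sex(sex) is Sex.MALE else c["f_female"]
    return (140.0 - age) * weight_used_kg * f / scr_umol_l


def _cg_estimate(
    method: str,
    patient: Patient,
    descriptor: WeightDescriptor,
    apply_scr_floor: bool,
    apply_cap: bool,
    constants: DosingConstants,
    coefficients: FormulaCoefficients,
) -> RenalEstimate:
    if descriptor == "ABW":
        weight_used = patient.weight_kg
    elif descriptor == "AIBW":
        weight_used = aibw(patient.sex, patient.height_cm, patient.weight_kg,
                           constants, coefficients)
    elif descriptor == "IBW":
        weight_used = ibw(patient.sex, patient.height_cm, coefficients)
    else:
        raise ValueError(f"unsupported weight descriptor {descriptor!r}")
    scr = patient.scr_umol_l
    floored = False
    if apply_scr_floor and scr < constants.scr_floor:
        scr = constants.scr_floor
        floored = True
    raw = cockcroft_gault(weight_used, patient.age, patient.sex, scr, coefficients)
    capped = apply_cap and raw > constants.crcl_cap
    return RenalEstimate(
        method=method,
        crcl=min(raw, constants.crcl_cap) if apply_cap else raw,
        raw_crcl=raw,
        weight_used=weight_used,
        weight_descriptor=descriptor,
        scr_floored=floored,
        crcl_capped=capped,
    )


def adjusted_cg(
    patient: Patient,
    constants: Optional[DosingConstants] = None,
    coefficients: Optional[FormulaCoefficients] = None,
) -> RenalEstimate:
    """The adjusted Cockcroft–Gault dosing algorithm (aCG): AIBW when
    BMI ≥ 25 kg/m², serum creatinine floored at 60 µmol/L, CrCL capped
    at 125 mL/min."""
    constants = constants or DosingConstants()
    coefficients = coefficients or _default_coeffs()
    descriptor: WeightDescriptor = (
        "AIBW" if patient.bmi >= constants.bmi_threshold else "ABW"
    )
    return _cg_estimate("aCG", patient, descriptor, True, True,
                        constants, coefficients)


def conventional_cg(
    patient: Patient,
    descriptor: WeightDescriptor = "ABW",
    capped: bool = False,
    constants: Optional[DosingConstants] = None,
    coefficients: Optional[FormulaCoefficients] = None,
) -> RenalEstimate:
    """Conventional Cockcroft–Gault with a fixed weight descriptor.

    The capped variant applies both the CrCL cap and the serum-creatinine
    floor; the uncapped variant applies neither.
    """
    constants = constants or DosingConstants()
    coefficients = coefficients or _default_coeffs()
    name = f"CG_{descriptor}" + ("_capped" if capped else "")
    return _cg_estimate(name, patient, descriptor, capped, capped,
                        constants, coefficients)


# ---------------------------------------------------------------------------
# Direct carboplatin-clearance models
# ---------------------------------------------------------------------------

def benezet_crcl(
    patient: Patient,
    constants: Optional[DosingConstants] = None,
    coefficients: Optional[FormulaCoefficients] = None,
) -> RenalEstimate:
    """Chatelut-type carboplatin clearance evaluated at min(ABW, IBW).

    Direct-clearance method: CL = θw·W + θr·W·(1 − a·age)·(1 − f·female)/Scr
    with W the smaller of absolute and ideal body weight.
    """
    constants = constants or DosingConstants()
    coefficients = coefficients or _default_coeffs()
    c = coefficients["chatelut_benezet"]
    w_ideal = ibw(patient.sex, patient.height_cm, coefficients)
    if patient.weight_kg <= w_ideal:
        weight_used, descriptor = patient.weight_kg, "ABW"
    else:
        weight_used, descriptor = w_ideal, "IBW"
    female = 1.0 if patient.sex is Sex.FEMALE else 0.0
    cl = (
        c["theta_weight"] * weight_used
        + c["theta_renal"] * weight_used * (1.0 - c["age_slope"] * patient.age)
        * (1.0 - c["female_factor"] * female) / patient.scr_umol_l
    )
    crcl = cl - constants.calvert_offset
    return RenalEstimate(
        method="benezet", crcl=crcl, raw_crcl=crcl, weight_used=weight_used,
        weight_descriptor=descriptor, direct_clearance=True,
    )


def schmitt_clearance(
    patient: Patient,
    constants: Optional[DosingConstants] = None,
    coefficients: Optional[FormulaCoefficients] = None,
) -> RenalEstimate:
    """Cystatin-C-based direct carboplatin-clearance power model.

    CL = θ · (CysC/ref)^a · (ABW/ref)^b · (age/ref)^c · (Scr/ref)^d · f^female.
    The clearance is returned as crcl = CL − calvert_offset with the
    direct-clearance flag set, so Calvert reconstruction is exact.
    """
    constants = constants or DosingConstants()
    coefficients = coefficients or _default_coeffs()
    if patient.cysc_mg_l is None:
        raise MissingCovariateError("schmitt", "cystatin C", patient.id)
    c = coefficients["schmitt"]
    female = patient.sex is Sex.FEMALE
    cl = (
        c["typical_cl_ml_min"]
        * (patient.cysc_mg_l / c["cysc_ref_mg_l"]) ** c["cysc_exp"]
        * (patient.weight_kg / c["weight_ref_kg"]) ** c["weight_exp"]
        * (patient.age / c["age_ref_yr"]) ** c["age_exp"]
        * (patient.scr_umol_l / c["scr_ref_umol_l"]) ** c["scr_exp"]
        * (c["female_factor"] if female else 1.0)
    )
    crcl = cl - constants.calvert_offset
    return RenalEstimate(
        method="schmitt", crcl=crcl, raw_crcl=crcl,
        weight_used=patient.weight_kg, weight_descriptor="ABW",
        direct_clearance=True,
    )


def flat_clearance(
    patient: Patient,
    constants: Optional[DosingConstants] = None,
    coefficients: Optional[FormulaCoefficients] = None,
) -> RenalEstimate:
    """Flat dosing: the mean population carboplatin clearance for everyone."""
    constants = constants or DosingConstants()
    crcl = constants.flat_population_cl - constants.calvert_offset
    return RenalEstimate(method="flat", crcl=crcl, raw_crcl=crcl,
                         direct_clearance=True)


# ---------------------------------------------------------------------------
# GFR estimators
# ---------------------------------------------------------------------------

UMOL_PER_L_PER_MG_PER_DL = 88.4


def ckdepi(
    patient: Patient,
    variant: Literal["creatinine", "creatinine_cystatin"] = "creatinine",
    deindex: bool = True,
    constants: Optional[DosingConstants] = None,
    coefficients: Optional[FormulaCoefficients] = None,
) -> RenalEstimate:
    """2021 race-free CKD-EPI eGFR.

    The equation yields mL/min/1.73 m²; with ``deindex`` (default) the value
    is multiplied by BSA/1.73 (Du Bois) to obtain absolute mL/min as required
    for the Calvert formula.
    """
    coefficients = coefficients or _default_coeffs()
    scr_mg_dl = patient.scr_umol_l / UMOL_PER_L_PER_MG_PER_DL
    female = patient.sex is Sex.FEMALE
    if variant == "creatinine":
        c = coefficients["ckdepi_creatinine"]
        kappa = c["kappa_female"] if female else c["kappa_male"]
        alpha = c["alpha_female"] if female else c["alpha_male"]
        r = scr_mg_dl / kappa
        egfr = (
            c["intercept"] * min(r, 1.0) ** alpha * max(r, 1.0) ** c["beta"]
            * c["age_base"] ** patient.age
            * (c["female_factor"] if female else 1.0)
        )
        name = "ckdepi_cr"
    elif variant == "creatinine_cystatin":
        if patient.cysc_mg_l is None:
            raise MissingCovariateError("ckdepi_cr_cys", "cystatin C", patient.id)
        c = coefficients["ckdepi_creatinine_cystatin"]
        kappa = c["kappa_female"] if female else c["kappa_male"]
        alpha = c["alpha_female"] if female else c["alpha_male"]
        r = scr_mg_dl / kappa
        s = patient.cysc_mg_l / c["cys_kappa"]
        egfr = (
            c["intercept"] * min(r, 1.0) ** alpha * max(r, 1.0) ** c["beta"]
            * min(s, 1.0) ** c["cys_alpha"] * max(s, 1.0) ** c["cys_beta"]
            * c["age_base"] ** patient.age
            * (c["female_factor"] if female else 1.0)
        )
        name = "ckdepi_cr_cys"
    else:
        raise ValueError(f"unknown CKD-EPI variant {variant!r}")
    if deindex:
        egfr *= bsa_dubois(patient.weight_kg, patient.height_cm, coefficients) / 1.73
    return RenalEstimate(method=name, crcl=egfr, raw_crcl=egfr,
                         weight_used=patient.weight_kg if deindex else None,
                         weight_descriptor="ABW" if deindex else "none")


def crcl_24h(ucr_mmol_24h: float, scr_umol_l: float) -> float:
    """Measured 24-h creatinine clearance, mL/min.

    Excretion rate (µmol/min) divided by serum concentration (µmol/L) gives
    L/min; ×1000 → mL/min.
    """
    if ucr_mmol_24h <= 0 or scr_umol_l <= 0:
        raise ValueError("urine creatinine and serum creatinine must be positive")
    return (ucr_mmol_24h * 1000.0 / 1440.0) / scr_umol_l * 1000.0


def crcl_24h_estimate(
    patient: Patient,
    constants: Optional[DosingConstants] = None,
    coefficients: Optional[FormulaCoefficients] = None,
) -> RenalEstimate:
    if patient.ucr_mmol_24h is None:
        raise MissingCovariateError("crcl_24h", "24-h urine creatinine", patient.id)
    v = crcl_24h(patient.ucr_mmol_24h, patient.scr_umol_l)
    return RenalEstimate(method="crcl_24h", crcl=v, raw_crcl=v)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

MethodFn = Callable[[Patient, DosingConstants, FormulaCoefficients], RenalEstimate]

METHODS: dict[str, MethodFn] = {
    "aCG": lambda p, k, c: adjusted_cg(p, k, c),
    "CG_ABW": lambda p, k, c: conventional_cg(p, "ABW", False, k, c),
    "CG_ABW_capped": lambda p, k, c: conventional_cg(p, "ABW", True, k, c),
    "CG_AIBW": lambda p, k, c: conventional_cg(p, "AIBW", False, k, c),
    "benezet": lambda p, k, c: benezet_crcl(p, k, c),
    "crcl_24h": lambda p, k, c: crcl_24h_estimate(p, k, c),
    "schmitt": lambda p, k, c: schmitt_clearance(p, k, c),
    "ckdepi_cr": lambda p, k, c: ckdepi(p, "creatinine", True, k, c),
    "ckdepi_cr_cys": lambda p, k, c: ckdepi(p, "creatinine_cystatin", True, k, c),
    "flat": lambda p, k, c: flat_clearance(p, k, c),
}


def evaluate_methods(
    patient: Patient,
    methods: Optional[list[str]] = None,
    constants: Optional[DosingConstants] = None,
    coefficients: Optional[FormulaCoefficients] = None,
) -> tuple[dict[str, RenalEstimate], dict[str, str]]:
    """Evaluate the registry on one patient.

    Returns (estimates, exclusions): a method missing a required covariate is
    excluded with its reason recorded, never silently imputed.
    """
    constants = constants or DosingConstants()
    coefficients = coefficients or _default_coeffs()
    estimates: dict[str, RenalEstimate] = {}
    exclusions: dict[str, str] = {}
    for name in methods or list(METHODS):
        try:
            estimates[name] = METHODS[name](patient, constants, coefficients)
        except MissingCovariateError as exc:
            log.info("patient %s excluded from %s: %s", patient.id, name, exc.covariate)
            exclusions[name] = f"missing {exc.covariate}"
    return estimates, exclusions
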