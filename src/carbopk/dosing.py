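"""Calvert dosing of carboplatin with clinical dose rounding.

dose = target AUC × (CrCL + 25 mL/min).  Administered doses are rounded to a
vial-compatible increment (default 50 mg); exact midpoints round down, the
toxicity-conservative choice.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .renal import DosingConstants, RenalEstimate

__all__ = ["DoseDecision", "calvert_dose", "round_dose", "flat_dose", "dose_patient",
           "write_doses", "read_doses"]

log = logging.getLogger(__name__)

DEFAULT_ROUNDING_INCREMENT = 50.0


@dataclass(frozen=True)
class DoseDecision:
    method: str
    target_auc: float
    crcl: float
    calculated_dose: float
    administered_dose: float
    rounding_increment: float


def calvert_dose(
    target_auc: float,
    estimate: RenalEstimate,
    constants: Optional[DosingConstants] = None,
) -> float:
    """Unrounded Calvert dose, mg: target × (crcl + offset).

    Direct-clearance estimates store clearance − offset in the crcl slot, so
    the same expression returns target × clearance for them.
    """
    constants = constants or DosingConstants()
    if target_auc < 0:
        raise ValueError("target AUC must be non-negative")
    if target_auc not in (0.0, 4.0, 5.0, 6.0):
        log.warning("target AUC %.2f outside the usual {4, 5, 6} range", target_auc)
    return target_auc * estimate.clearance(constants)


def round_dose(dose_mg: float, increment_mg: float = DEFAULT_ROUNDING_INCREMENT) -> float:
    """Round to the nearest multiple of ``increment_mg``; midpoints round down."""
    if dose_mg < 0:
        raise ValueError("dose must be non-negative")
    if increment_mg <= 0:
        raise ValueError("rounding increment must be positive")
    return math.ceil(dose_mg / increment_mg - 0.5) * increment_mg


def flat_dose(
    target_auc: float,
    constants: Optional[DosingConstants] = None,
    increment_mg: float = DEFAULT_ROUNDING_INCREMENT,
) -> float:
    """Flat dose from the mean population clearance, rounded."""
    constants = constants or DosingConstants()
    if target_auc < 0:
        raise ValueError("target AUC must be non-negative")
    return round_dose(target_auc * constants.flat_population_cl, increment_mg)


def dose_patient(
    target_auc: float,
    estimate: RenalEstimate,
    constants: Optional[DosingConstants] = None,
    increment_mg: Optional[float] = DEFAULT_ROUNDING_INCREMENT,
) -> DoseDecision:
    """Full dose decision for one patient/method; ``increment_mg=None``
    disables rounding."""
    constants = constants or DosingConstants()
    calculated = calvert_dose(target_auc, estimate, constants)
    if increment_mg is None:
        administered, inc = calculated, 0.0
    else:
        administered, inc = round_dose(calculated, increment_mg), increment_mg
    return DoseDecision(
        method=estimate.method,
        target_auc=target_auc,
        crcl=estimate.crcl,
        calculated_dose=calculated,
        administered_dose=administered,
        rounding_increment=inc,
    )


DOSE_COLUMNS = ["id", "method", "target_auc", "crcl_ml_min",
                "calculated_dose_mg", "administered_dose_mg"]


def write_doses(rows: Sequence[tuple[str, DoseDecision]], path) -> None:
    """Write a dosing table CSV of (patient id, decision) pairs."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(DOSE_COLUMNS)
        for pid, d in rows:
            w.writerow([pid, d.method, format(d.target_auc, ".17g"),
                        format(d.crcl, ".17g"),
                        format(d.calculated_dose, ".17g"),
                        format(d.administered_dose, ".17g")])


def read_doses(path) -> dict[str, DoseDecision]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in DOSE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"dose file missing column(s): {missing}")
        out = {}
        for row in reader:
            calc = float(row["calculated_dose_mg"])
            adm = float(row["administered_dose_mg"])
            out[row["id"]] = DoseDecision(
                method=row["method"],
                target_auc=float(row["target_auc"]),
                crcl=float(row["crcl_ml_min"]),
                calculated_dose=calc,
                administered_dose=adm,
                rounding_increment=0.0,
            )
        return out
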