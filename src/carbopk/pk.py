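"""Closed-form two-compartment kinetics of ultrafilterable carboplatin.

The drug enters the central compartment (volume V1, clearance CL) by a
zero-order infusion and distributes to a peripheral compartment (V2) with
inter-compartmental clearance Q.  Micro constants k10 = CL/V1, k12 = Q/V1,
k21 = Q/V2 give the biexponential macro constants α > β > 0 as roots of
s² − (k10+k12+k21)s + k10·k21 = 0.

Internal canonical units are mg, mL and min throughout; concentrations are
mg/mL.  AUC to infinity is dose/CL exactly, independent of the volumes.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PKParameters", "VarianceModel", "DosingEvent", "ConcObservation",
    "concentration", "auc_inf", "default_schedule", "simulate_observations",
    "write_concentrations", "read_concentrations",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PKParameters:
    """Individual or population two-compartment parameters (mL, mL/min)."""

    cl: float = 112.4          # carboplatin clearance, mL/min
    v1: float = 20_000.0       # central volume, mL
    q: float = 500.0           # inter-compartmental clearance, mL/min
    v2: float = 20_000.0       # peripheral volume, mL

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "q", "v2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def k10(self) -> float:
        return self.cl / self.v1

    @property
    def k12(self) -> float:
        return self.q / self.v1

    @property
    def k21(self) -> float:
        return self.q / self.v2

    @property
    def macro_constants(self) -> tuple[float, float]:
        """(α, β) with α ≥ β > 0."""
        s = self.k10 + self.k12 + self.k21
        p = self.k10 * self.k21
        disc = math.sqrt(max(s * s - 4.0 * p, 0.0))
        alpha = (s + disc) / 2.0
        beta = p / alpha  # product form: numerically stable for small β
        return alpha, beta


@dataclass(frozen=True)
class VarianceModel:
    """Log-normal IIV (diagonal Ω) and combined residual error.

    omega_cl / omega_v1 are log-scale SDs of the random effects on CL and V1
    (omega_v1 = 0 disables that effect); sigma_prop is the proportional
    residual SD (fraction), sigma_add the additive residual SD (mg/mL).
    """

    omega_cl: float = 0.2
    omega_v1: float = 0.0
    sigma_prop: float = 0.10
    sigma_add: float = 0.0

    def __post_init__(self) -> None:
        for name in ("omega_cl", "omega_v1", "sigma_prop", "sigma_add"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DosingEvent:
    dose: float                     # mg
    infusion_duration: float = 30.0  # min

    def __post_init__(self) -> None:
        if self.dose <= 0 or self.infusion_duration <= 0:
            raise ValueError("dose and infusion duration must be positive")


@dataclass(frozen=True)
class ConcObservation:
    patient_id: str
    time: float      # min since infusion start
    conc: float      # mg/mL
    is_predose: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if self.conc < 0:
            raise ValueError("concentration must be >= 0")


def _step_response(t: np.ndarray, params: PKParameters, rate: float) -> np.ndarray:
    """Central concentration under an infusion at ``rate`` starting at 0 and
    never stopping, evaluated at t ≥ 0 (t < 0 contributes 0)."""
    alpha, beta = params.macro_constants
    k21 = params.k21
    t = np.maximum(t, 0.0)
    if (alpha - beta) > 1e-9 * alpha:
        a = (alpha - k21) / (params.v1 * (alpha - beta))   # bolus coeff on e^{-αt}
        b = (k21 - beta) / (params.v1 * (alpha - beta))    # bolus coeff on e^{-βt}
        return rate * (a / alpha * (1.0 - np.exp(-alpha * t))
                       + b / beta * (1.0 - np.exp(-beta * t)))
    # repeated root: bolus response D/V1·e^{-αt}(1 + (k21−α)t); integrate
    lam = alpha
    e = np.exp(-lam * t)
    return rate / params.v1 * ((1.0 - e) / lam
                               + (k21 - lam) * (1.0 - e * (1.0 + lam * t)) / lam ** 2)


def concentration(t, params: PKParameters, event: DosingEvent):
    """Central-compartment concentration (mg/mL) at time t (min since
    infusion start). Accepts a scalar or array; continuous at t = duration
    by construction (the finite infusion is a step minus a delayed step)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    rate = event.dose / event.infusion_duration
    c = _step_response(t_arr, params, rate) - _step_response(
        t_arr - event.infusion_duration, params, rate
    )
    c = np.maximum(c, 0.0)  # clip tiny negative round-off
    return float(c) if np.isscalar(t) or t_arr.ndim == 0 else c


def auc_inf(dose: float, params: PKParameters) -> float:
    """AUC from zero to infinity, mg·min/mL: dose / CL exactly."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return dose / params.cl


def default_schedule(event: DosingEvent) -> list[tuple[float, bool]]:
    """The sparse study design: one predose sample, one at the end of the
    infusion, and one at 1, 2.5 and 5 h after the end of the infusion.
    Returns (time since infusion start, is_predose) pairs."""
    T = event.infusion_duration
    return [(0.0, True), (T, False), (T + 60.0, False),
            (T + 150.0, False), (T + 300.0, False)]


def simulate_observations(
    patient_params: PKParameters,
    event: DosingEvent,
    schedule: Optional[Sequence[tuple[float, bool]]] = None,
    variance: Optional[VarianceModel] = None,
    seed=0,
    patient_id: str = "SIM",
) -> list[ConcObservation]:
    """Simulate noisy observations: y = C(t)(1+ε_p) + ε_a, truncated at 0.

    A predose sample on the first cycle carries no drug, so its simulated
    concentration is exactly 0.  ``seed`` may be an int or a numpy SeedSequence
    key; negative residual draws are truncated at zero with a logged count.
    """
    variance = variance or VarianceModel()
    if schedule is None:
        schedule = default_schedule(event)
    if not schedule:
        raise ValueError("schedule must be non-empty")
    rng = np.random.default_rng(seed)
    out = []
    n_truncated = 0
    for t, predose in schedule:
        c = 0.0 if predose else float(concentration(t, patient_params, event))
        y = c
        if variance.sigma_prop > 0:
            y = y * (1.0 + rng.normal(0.0, variance.sigma_prop))
        if variance.sigma_add > 0:
            y = y + rng.normal(0.0, variance.sigma_add)
        if y < 0:
            y = 0.0
            n_truncated += 1
        out.append(ConcObservation(patient_id, t, y, predose))
    if n_truncated:
        log.info("patient %s: %d negative draws truncated at 0", patient_id, n_truncated)
    return out


# ---------------------------------------------------------------------------
# Concentration CSV I/O
# ---------------------------------------------------------------------------

CONC_COLUMNS = ["patient_id", "time_min", "conc", "unit"]
_UNIT_TO_MG_ML = {"mg/mL": 1.0, "ug/mL": 1e-3, "µg/mL": 1e-3, "mg/L": 1e-3}


def write_concentrations(obs: Sequence[ConcObservation], path, unit="mg/mL") -> None:
    scale = _UNIT_TO_MG_ML[unit]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CONC_COLUMNS)
        for o in obs:
            w.writerow([o.patient_id, format(o.time, ".17g"),
                        format(o.conc / scale, ".17g"), unit])


def read_concentrations(path) -> list[ConcObservation]:
    """Read a concentration CSV, normalising units to mg/mL. The earliest
    sample of each patient at time 0 is flagged predose."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in CONC_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"concentration file missing column(s): {missing}")
        rows = []
        for i, row in enumerate(reader, start=2):
            unit = row["unit"]
            if unit not in _UNIT_TO_MG_ML:
                raise ValueError(f"line {i}: unknown concentration unit {unit!r}")
            rows.append((row["patient_id"], float(row["time_min"]),
                         float(row["conc"]) * _UNIT_TO_MG_ML[unit]))
    seen_predose: set[str] = set()
    out = []
    for pid, t, c in rows:
        predose = t == 0.0 and pid not in seen_predose
        if predose:
            seen_predose.add(pid)
        out.append(ConcObservation(pid, t, c, predose))
    return out
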