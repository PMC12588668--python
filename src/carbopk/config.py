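"""Run configuration: one TOML file driving a whole simulation study.

Sections (all optional, defaults apply):

    [constants]   calvert_offset, crcl_cap, scr_floor, bmi_threshold,
                  flat_population_cl, aibw_factor
    [pk]          cl, v1, q, v2, infusion_duration
    [variance]    omega_cl, omega_v1, sigma_prop, sigma_add
    [cohort]      omega_cl, ucr_noise_cv, truth_method, seed,
                  target_auc_choices, target_auc_probs,
                  p_missing_cysc, p_missing_ucr,
                  plus per-stratum tables [cohort.strata."<25.0"] etc. with
                  n, age_range, weight_range, height_range, scr_range,
                  cysc_range, p_male
    [evaluation]  auc_mode, rounding_increment, dosing_method

The resolved configuration is logged at load so every run is reproducible
from its log alone.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from typing import Any, Optional

from .cohort import CohortSpec, Stratum, StratumSpec
from .pk import PKParameters, VarianceModel
from .renal import DosingConstants

__all__ = ["RunConfig", "load_run_config"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    constants: DosingConstants
    pop_params: PKParameters
    infusion_duration: float
    variance: VarianceModel
    cohort_spec: CohortSpec
    auc_mode: str = "counterfactual"
    rounding_increment: Optional[float] = 50.0
    dosing_method: str = "aCG"


def _pick(data: dict[str, Any], cls, **extra):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} config key(s): {sorted(unknown)}")
    return cls(**{**data, **extra})


def _cohort_spec(section: dict[str, Any], seed: Optional[int]) -> CohortSpec:
    section = dict(section)
    strata_cfg = section.pop("strata", None)
    kwargs: dict[str, Any] = {}
    for key in ("omega_cl", "ucr_noise_cv", "truth_method", "seed",
                "p_missing_cysc", "p_missing_ucr"):
        if key in section:
            kwargs[key] = section.pop(key)
    for key in ("target_auc_choices", "target_auc_probs"):
        if key in section:
            kwargs[key] = tuple(section.pop(key))
    if section:
        raise ValueError(f"unknown [cohort] config key(s): {sorted(section)}")
    if strata_cfg is not None:
        strata = {}
        for code, cfg in strata_cfg.items():
            stratum = Stratum(code)
            cfg = {k: tuple(v) if isinstance(v, list) else v for k, v in cfg.items()}
            strata[stratum] = _pick(cfg, StratumSpec)
        kwargs["strata"] = strata
    if seed is not None:
        kwargs["seed"] = seed
    return CohortSpec(**kwargs)


def load_run_config(path=None, seed: Optional[int] = None) -> RunConfig:
    """Load a run configuration; ``seed`` (e.g. from the CLI) overrides the
    seed in the file. ``path=None`` yields all defaults."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    constants = _pick(data.get("constants", {}), DosingConstants)
    pk_section = dict(data.get("pk", {}))
    infusion_duration = float(pk_section.pop("infusion_duration", 30.0))
    pop_params = _pick(pk_section, PKParameters)
    variance = _pick(data.get("variance", {}), VarianceModel)
    cohort_spec = _cohort_spec(data.get("cohort", {}), seed)
    ev = dict(data.get("evaluation", {}))
    auc_mode = ev.pop("auc_mode", "counterfactual")
    if auc_mode not in ("counterfactual", "predicted"):
        raise ValueError(f"unknown auc_mode {auc_mode!r}")
    rounding = ev.pop("rounding_increment", 50.0)
    rounding = None if rounding in (0, 0.0, "off") else float(rounding)
    dosing_method = ev.pop("dosing_method", "aCG")
    if ev:
        raise ValueError(f"unknown [evaluation] config key(s): {sorted(ev)}")
    cfg = RunConfig(constants=constants, pop_params=pop_params,
                    infusion_duration=infusion_duration, variance=variance,
                    cohort_spec=cohort_spec, auc_mode=auc_mode,
                    rounding_increment=rounding, dosing_method=dosing_method)
    log.info("run config resolved: %s", cfg)
    return cfg
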