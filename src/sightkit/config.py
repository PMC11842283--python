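"""Run configuration: a validated YAML-backed settings object.

Unknown keys are rejected, units are fixed by the field names (values are
plain numbers, never unit-suffixed strings), and the provenance of every
defaulted field is logged when a file is loaded.
"""
from __future__ import annotations

import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .compounds import MediumSpec
from .errors import ConfigError
from .partition import VialSystem

__all__ = ["RunConfig", "ScheduleConfig", "AnalysisConfig", "load_config", "dump_config"]

logger = logging.getLogger("sightkit")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScheduleConfig(_Strict):
    c_start_mM: float = 1.0
    increment_mM: float = 0.25
    second_phase_fraction: float = 1.0
    n_second_phase_cycles: int = 2
    include_saturation_cycle: bool = False


class AnalysisConfig(_Strict):
    baseline_points: int = 3
    rate_window: int = 5
    lag_fraction: float = 0.05
    rate_min_fraction: float = 0.2
    stationary_fraction: float = 0.95


class RunConfig(_Strict):
    """Top-level configuration consumed by the command-line interface."""

    compound: str = "styrene"
    v_total_ml: float = 4.937
    v_medium_ml: float = 0.600
    temperature_c: float = 30.0
    pressure_kpa: float = 101.3
    glucose_mM: float = 20.0
    o2_solubility_mg_l: float = 9.1
    biomass_yield: float = 0.396
    inoculum_od: float = 0.05
    schedule: ScheduleConfig = ScheduleConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    output_dir: str = "sightkit-out"
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check_geometry(self) -> "RunConfig":
        if not 0 < self.v_medium_ml < self.v_total_ml:
            raise ValueError(
                f"require 0 < v_medium_ml < v_total_ml, got "
                f"v_medium_ml={self.v_medium_ml}, v_total_ml={self.v_total_ml}"
            )
        return self

    def vial_system(self) -> VialSystem:
        return VialSystem(
            v_total=self.v_total_ml,
            v_medium=self.v_medium_ml,
            temperature=self.temperature_c,
            pressure=self.pressure_kpa,
        )

    def medium(self) -> MediumSpec:
        return MediumSpec(
            glucose_conc=self.glucose_mM, o2_solubility=self.o2_solubility_mg_l
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; defaults fill missing keys.

    Raises :class:`ConfigError` naming the offending key on unknown keys,
    unit-suffixed (non-numeric) values, or out-of-range values.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    try:
        cfg = RunConfig(**raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc']) or '<root>'}: {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigError(f"{path}: invalid configuration — {details}") from exc
    defaulted = sorted(set(RunConfig.model_fields) - cfg.model_fields_set)
    if defaulted:
        logger.debug("config %s: defaults used for %s", path, ", ".join(defaulted))
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=True)
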