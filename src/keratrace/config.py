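"""Run configuration: one human-readable YAML file validated strictly
(unknown keys rejected with the offending key named)."""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .cohort import CohortConfig
from .errors import ConfigError
from .formulas import FormulaConstants
from .tracing import GridSpec

__all__ = ["RunConfig", "IOConfig", "ReportConfig", "load_config", "config_hash"]


class IOConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    outdir: str = "results"
    cohort_csv: str = "cohort.csv"
    plot_format: str = "png"


class ReportConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    alpha: float = 0.05
    plot_methods: tuple[str, ...] = (
        "Km",
        "K_Haigis",
        "K_Shammas",
        "TNP",
        "EKR_4.0",
        "EKR_4.5",
        "TCRP_pupil_zone_4.0",
        "TCRP_apex_zone_4.0",
        "TCRP_pupil_ring_4.0",
        "TCRP_apex_ring_4.0",
        "modTCRP_pupil_zone_4.0",
        "modTCRP_apex_zone_4.0",
    )


class RunConfig(BaseModel):
    """Everything one pipeline run depends on."""

    model_config = ConfigDict(extra="forbid")

    cohort: CohortConfig = CohortConfig()
    grid: GridSpec = GridSpec(meridians=64)
    formulas: FormulaConstants = FormulaConstants()
    io: IOConfig = IOConfig()
    report: ReportConfig = ReportConfig()


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc


def config_hash(cfg: RunConfig) -> str:
    """Short stable digest of the full configuration."""
    blob = cfg.model_dump_json().encode()
    return hashlib.sha256(blob).hexdigest()[:12]
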