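"""Run configuration: schema, validation, (de)serialization."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, ValidationError

from .errors import ConfigError


class NoiseConfig(BaseModel):
    pressure_sd: float = Field(1.0, ge=0, description="mmHg, additive on pressures")
    volume_sd: float = Field(2.0, ge=0, description="raw units, additive on volume")


class RunConfig(BaseModel):
    """Validated configuration for the end-to-end pipeline."""

    seed: int
    n_pigs: int = Field(10, ge=2)
    fs: float = Field(250.0, gt=0)
    stage_duration_s: float = Field(30.0, gt=0)
    summary_window_s: float = Field(10.0, gt=0)
    level: str = Field("trace", pattern="^(trace|summary)$")
    noise: NoiseConfig = NoiseConfig()
    heteroscedastic_variances: bool = True
    include_period_term: bool = False
    out_dir: str = "results"
    reference_stage: str = "impella"
    table2_variables: list[str] = [
        "SW", "PE", "PVA", "HR", "cardiac_work_e3", "LVEDP", "LVEDV",
        "LVESP", "LVESV", "Ees", "Ea", "Ea_over_Ees", "MAP", "RAP",
        "mPAP", "Hb",
    ]
    perfusion_variables: list[str] = [
        "SvO2", "renal_vO2", "cerebral_vO2", "arterial_lactate",
    ]

    model_config = {"extra": "forbid"}


def validate_config(path: str | Path) -> RunConfig:
    """Load and fully validate a JSON config, collecting *all* violations."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise ConfigError(f"config is not valid JSON: {err}") from err
    try:
        return RunConfig(**payload)
    except ValidationError as err:
        items = [
            f"{'.'.join(str(p) for p in e['loc']) or '<root>'}: {e['msg']}"
            for e in err.errors()
        ]
        raise ConfigError(
            "config validation failed:\n  " + "\n  ".join(items), errors=items
        ) from err
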