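"""Pipeline configuration: YAML schema, validation and hashing."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError


class BeamSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    nominal_MV: Literal[6, 10]
    filtered: bool = True
    field_size: float = Field(5.0, gt=0)
    ssd: float = Field(90.0, gt=0)


class RunSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    histories: int = Field(2_000_000, ge=1)
    seed: int = Field(12345, ge=0)
    cutoff_energy: float = Field(0.01, ge=0.001)
    electron_mode: Literal["local", "csda_line"] = "local"


class PhantomSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    with_lipiodol: bool = True
    paired: bool = True  # also run the all-water companion for DEF


class AnalysisSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bin_mode: Literal["log", "linear50"] = "log"
    peg_variant: Literal["muen", "ratio"] = "muen"


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    beam: BeamSection
    run: RunSection = RunSection()
    phantom: PhantomSection = PhantomSection()
    analysis: AnalysisSection = AnalysisSection()
    output_dir: str = "results"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class ConfigError(ValueError):
    """Invalid configuration, with the offending field path in the message."""


def load_config(path: str | Path, overrides: Optional[dict] = None) -> PipelineConfig:
    """Load and validate a YAML config file; CLI overrides win."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        for dotted, value in overrides.items():
            node = raw
            keys = dotted.split(".")
            for k in keys[:-1]:
                node = node.setdefault(k, {})
            node[keys[-1]] = value
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"{loc}: {err['msg']}")
        raise ConfigError(
            "invalid configuration:\n  " + "\n  ".join(lines)
        ) from exc
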