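"""Pipeline configuration.

A single YAML file drives every stage; unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class PipelineConfig(BaseModel):
    """All tunables of the map-processing pipeline.

    QC thresholds are advisory screening bounds for individual maps;
    cycle caps bound the feedback-loop enumeration (the loop-existence
    answer itself comes from the exact strongly-connected-component test
    and is never capped).
    """

    model_config = ConfigDict(extra="forbid")

    # QC thresholds
    diameter_floor: int = Field(5, ge=1)
    source_fraction_ceiling: float = Field(0.5, ge=0.0, le=1.0)
    density_ceiling: float = Field(0.05, ge=0.0, le=1.0)

    # cycle enumeration caps
    cycle_max_len: int = Field(7, ge=2)
    cycle_cap: int = Field(10_000, ge=1)

    # IO
    diameter_mode: str = Field("directed", pattern="^(directed|undirected)$")
    output_format: str = Field("edgelist-csv", pattern="^(edgelist-csv|graphml|json)$")
    flatten_thesaurus: bool = False

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def digest(self) -> str:
        """Stable hash of the configuration, for run logs."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
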