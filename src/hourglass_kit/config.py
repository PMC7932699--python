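"""Pipeline configuration: every threshold in one validated, hashable object."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field


class PipelineConfig(BaseModel):
    """All tunable knobs of the two workflows; unknown keys are rejected.

    Thresholds default to the analysis' published operating point: expression
    floor 1.0 TPM, heterochrony |PCC| 0.5, stage-association |z| 1.0, tissue
    entropy 0.65, conservation score 40, reciprocal bin overlap 0.4, motif
    score fraction 0.75, FRiP QC 0.2.
    """

    model_config = ConfigDict(extra="forbid")

    species_a: str = "species_a"
    species_b: str = "species_b"
    stages_a: list[str] = Field(
        default_factory=lambda: ["st27", "st27.5", "st29", "st30", "st31", "st32"]
    )
    stages_b: list[str] = Field(
        default_factory=lambda: ["E9.5", "E10.5", "E11.5", "E12.5"]
    )
    scaling_method: Literal["max1", "zscore", "unitvec", "log10"] = "max1"
    metrics: list[Literal["euclidean", "correlation", "shannon", "std_euclidean"]] = (
        Field(default_factory=lambda: ["euclidean", "correlation", "shannon", "std_euclidean"])
    )
    tpm_min: float = Field(1.0, ge=0)
    pcc_thr: float = Field(0.5, ge=0, le=1)
    z_min: float = Field(1.0, ge=0)
    h_thr: float = Field(0.65, ge=0)
    entropy_direction: Literal["ge", "le"] = "ge"
    score_min: float = Field(40.0, ge=0)
    min_frac: float = Field(0.4, ge=0, le=1)
    frac_motif: float = Field(0.75, ge=0, le=1)
    alpha: float = Field(0.05, gt=0, lt=1)
    frip_qc_min: float = Field(0.2, ge=0, le=1)
    bin_width_samples: int = Field(500, gt=0)
    bin_width_conservation: int = Field(100, gt=0)
    log_base: Literal["natural"] = "natural"
    sem_ddof: int = Field(1, ge=0, le=1)
    zscore_ddof: int = Field(0, ge=0, le=1)
    evalue_max: float | None = 1e-30
    n_clusters: int = Field(7, gt=1)
    seed: int = 0
    out_dir: str = "results"

    def config_hash(self) -> str:
        """Stable hash over semantically meaningful fields (out_dir excluded)."""
        payload = self.model_dump()
        payload.pop("out_dir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
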