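"""Run configuration: one YAML-serialisable schema holding every threshold.

All pipeline constants live here with their conventional defaults — the
2.5-SD / 2-probe / 2-replicate peak rule, the 2-fold dual response filter,
the 5-fold top-table cut, the 250 bp promoter window and the 6 bp operator
spacer — and every one is overridable.  Unknown keys are rejected so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class PeaksConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_sd: float = 2.5
    min_run: int = 2
    min_replicates: int = 2
    max_probe_gap_bp: int | None = None
    use_log_ratio: bool = False
    pooled: bool = False


class ExpressionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    theta: float = 2.0              # dual response filter
    theta_top: float = 5.0          # top-table / strong-dependence cut
    theta_responsive_mutant: float = 2.0
    wt_strain: str = "WT"
    mutant_strain: str = "glnR"
    anova_alpha: float = 0.05


class MotifConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    half_site_a: str = "GTNAC"
    half_site_b: str = "GTNAC"
    spacer_min: int = 6
    spacer_max: int = 6
    window: int = 250
    pseudocount: float = 0.5


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    replicon_length: int = 1_000_000
    n_genes: int = 300
    probe_spacing: int = 180
    probe_length: int = 60
    n_planted_sites: int = 20
    n_artefact_sites: int = 3
    chip_noise_sd_log2: float = 0.25
    expr_noise_sd_log2: float = 0.25
    n_chip_replicates: int = 2
    n_dependent: int = 30
    n_independent: int = 30
    n_null: int = 200


class RunConfig(BaseModel):
    """Top-level pipeline configuration (YAML round-trips losslessly)."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 1
    outdir: str = "results"
    peaks: PeaksConfig = Field(default_factory=PeaksConfig)
    expression: ExpressionConfig = Field(default_factory=ExpressionConfig)
    motif: MotifConfig = Field(default_factory=MotifConfig)
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.model_dump(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        text = yaml.safe_dump(self.model_dump(exclude={"outdir"}),
                              sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]
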