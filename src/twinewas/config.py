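"""Pipeline configuration: a validated, nested key/value structure.

Loaded from YAML; unknown keys are rejected so typos fail before any
compute.  Every numeric default matches the corresponding module default.
"""
from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class QcConfig(_Strict):
    min_mean_beta: float = Field(0.01, gt=0)
    max_missing: int = Field(10, ge=0)
    coverage_quantile: float = Field(0.9, gt=0, lt=1)
    bp_sd_limit: float = Field(3.0, gt=0)


class CellmixConfig(_Strict):
    k: int = Field(5, gt=0)
    t: int = Field(500, gt=0)
    d: int = Field(5, gt=0)


class EwasConfig(_Strict):
    orientation: str = "m_on_bp"
    working: str = "exchangeable"
    min_pairs: int = Field(10, gt=0)


class DmrConfig(_Strict):
    seed_p: float = Field(1e-4, gt=0, lt=1)
    window: int = Field(200, gt=0)
    max_gap: int = Field(200, gt=0)
    bin_size: int = Field(50, gt=0)
    max_dist: int = Field(500, gt=0)
    alpha: float = Field(0.05, gt=0, lt=1)


class IceFalconConfig(_Strict):
    n_boot: int = Field(1000, gt=0)
    ratio_threshold: float = Field(1.5, gt=0)
    alpha: float = Field(0.05, gt=0, lt=1)
    top_p: float = Field(1e-4, gt=0, lt=1)


class PathsConfig(_Strict):
    methylation: str
    phenotypes: str
    coverage: str | None = None
    genes: str | None = None
    outdir: str = "twinewas_run"


class PipelineConfig(_Strict):
    trait: str = "SBP"
    discordance_min_diff: float | None = Field(None, gt=0)
    qc: QcConfig = QcConfig()
    cellmix: CellmixConfig = CellmixConfig()
    ewas: EwasConfig = EwasConfig()
    dmr: DmrConfig = DmrConfig()
    icefalcon: IceFalconConfig = IceFalconConfig()
    seed: int = 0
    paths: PathsConfig

    @model_validator(mode="after")
    def _check(self):
        if self.trait.upper() not in ("SBP", "DBP"):
            raise ValueError("trait must be SBP or DBP")
        if self.dmr.max_dist < self.dmr.bin_size:
            raise ValueError("dmr.max_dist must be >= dmr.bin_size")
        if self.ewas.orientation not in ("m_on_bp", "bp_on_m"):
            raise ValueError("ewas.orientation must be m_on_bp or bp_on_m")
        if self.ewas.working not in ("exchangeable", "independence"):
            raise ValueError("ewas.working must be exchangeable or independence")
        return self


def load_config(path, overrides: dict | None = None) -> PipelineConfig:
    """Read a YAML config file, apply flat dotted-key overrides, validate."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        node = raw
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    return PipelineConfig(**raw)
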