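"""Validated pipeline configuration and run manifests.

Defaults mirror the published analysis settings (QC cutoffs, the Ea gene
filter, NNMF with k = 25 and ten restarts, the 50%-overlap/5-patient factor
exclusion, 25 expression bins with 100 control genes per signature gene,
the 0.6 correlation cut for meta-signatures, and p < 0.1 for survival
contrasts), so a bare run reproduces the published configuration. Unknown
keys are rejected before any stage runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class QcConfig(_Section):
    min_reads: int = Field(100_000, ge=0)
    min_genes: int = Field(1000, ge=0)
    max_mito: float = Field(0.15, ge=0.0, le=1.0)
    top_read_quantile: float = Field(0.05, ge=0.0, le=1.0)
    pca_outlier_sd: float | None = None


class NormalizeConfig(_Section):
    min_ea: float = 3.5


class Lgr5Config(_Section):
    gene: str = "LGR5"
    threshold: float = 1.0
    restrict_to_positive: bool = True


class NnmfConfig(_Section):
    k: int = Field(25, ge=1)
    n_restarts: int = Field(10, ge=1)
    max_iter: int = Field(500, ge=1)
    tol: float = Field(1e-4, gt=0.0)


class FactorFilterConfig(_Section):
    overlap_threshold: float = Field(0.5, ge=0.0, le=1.0)
    min_patients: int = Field(5, ge=1)
    n_bins: int = Field(50, ge=2)


class ScoringConfig(_Section):
    top_n_genes: int = Field(200, ge=1)
    n_bins: int = Field(25, ge=1)
    n_control_per_gene: int = Field(100, ge=1)


class MetaConfig(_Section):
    r_threshold: float = Field(0.6, ge=-1.0, le=1.0)


class SurvivalConfig(_Section):
    alpha: float = Field(0.1, gt=0.0, le=1.0)


class PipelineConfig(_Section):
    """All stage parameters, validated against this schema."""

    seed: int = 0
    qc: QcConfig = Field(default_factory=QcConfig)
    normalize: NormalizeConfig = Field(default_factory=NormalizeConfig)
    lgr5: Lgr5Config = Field(default_factory=Lgr5Config)
    nnmf: NnmfConfig = Field(default_factory=NnmfConfig)
    factor_filter: FactorFilterConfig = Field(default_factory=FactorFilterConfig)
    scoring: ScoringConfig = Field(default_factory=ScoringConfig)
    meta: MetaConfig = Field(default_factory=MetaConfig)
    survival: SurvivalConfig = Field(default_factory=SurvivalConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        from .io import atomic_write

        with atomic_write(path) as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)


def synthetic_pipeline_config(seed: int = 0, k: int = 10) -> PipelineConfig:
    """Configuration tuned to the scale of the synthetic cohorts.

    A simulated cohort has ~2000 genes and counts libraries of ~10^4, so
    the aggregate-expression cutoff sits lower than on genome-wide data and
    the factor count matches the handful of planted programs.
    """
    cfg = PipelineConfig(seed=seed)
    cfg.normalize.min_ea = 2.0
    cfg.nnmf.k = k
    cfg.nnmf.max_iter = 300
    cfg.factor_filter.min_patients = 5
    return cfg


@dataclass
class RunManifest:
    """Reproducibility record: digests in, config, seeds, outputs."""

    input_digests: dict[str, str]
    config: dict
    seed: int
    stages: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def add_stage(self, name: str, **summary) -> None:
        self.stages.append({"stage": name, **summary})

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True, default=str)
        if path is not None:
            from .io import atomic_write

            with atomic_write(path) as fh:
                fh.write(text + "\n")
        return text


def digest_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def digest_array(arr) -> str:
    import numpy as np

    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()
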