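"""Run configuration for the command-line pipeline.

A YAML file is validated strictly (unknown keys rejected) into a pydantic
model and re-serialized into every output directory for provenance.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PathsConfig(_Strict):
    genotypes: str | None = None
    genotype_format: str = "csv_dosage"
    genotype_map: str | None = None
    phenotypes: str | None = None
    outdir: str = "saltgp_out"


class FilterConfig(_Strict):
    min_call_rate: float = 0.75
    max_het_rate: float = 0.10
    min_maf: float = 0.05
    impute_method: str = "mode"
    prune: bool = True


class KernelConfig(_Strict):
    method: str = "GBLUP"  # GBLUP | RKHS
    bandwidth: float | None = None
    bandwidth_prior_shape: float = 3.0
    bandwidth_prior_scale: float = 1.5


class MCMCConfig(_Strict):
    n_iter: int = 35_000
    burn_in: int = 5_000
    thin: int = 10
    n_chains: int = 1
    df0: float = 5.0
    r2: float = 0.5
    pooled_residual: bool = False


class CVConfig(_Strict):
    n_reps: int = 100
    fraction: float = 0.8
    model: str = "single"  # single | multi
    traits: list[str] | None = None


class SelectionConfig(_Strict):
    traits: list[str] = Field(default_factory=lambda: ["Na", "K", "Na_K", "iSHOOT", "iROOT"])
    methods: list[str] = Field(default_factory=lambda: ["GBLUP", "RKHS"])
    n_sel: int = 41
    tail_q: float = 0.10
    proportions: list[float] = Field(default_factory=lambda: [0.2, 0.2, 0.6])


class SimulateConfig(_Strict):
    n_individuals: int = 600
    n_markers: int = 17_000
    n_chromosomes: int = 12
    fst: float = 0.1
    admixture_fraction: float = 0.37
    n_causal: int = 300
    missing_rate: float = 0.0
    het_rate: float = 0.0


class StructureConfig(_Strict):
    k: int = 3
    var_explained: float = 0.90
    n_restarts: int = 10


class RunConfig(_Strict):
    paths: PathsConfig = Field(default_factory=PathsConfig)
    filters: FilterConfig = Field(default_factory=FilterConfig)
    kernel: KernelConfig = Field(default_factory=KernelConfig)
    mcmc: MCMCConfig = Field(default_factory=MCMCConfig)
    cv: CVConfig = Field(default_factory=CVConfig)
    selection: SelectionConfig = Field(default_factory=SelectionConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    structure: StructureConfig = Field(default_factory=StructureConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
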