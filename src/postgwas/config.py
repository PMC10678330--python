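"""Pipeline configuration.

All thresholds default to the full-scale study settings: genome-wide
significance 1e-8, LD window +/- 500 kb at r^2 > 0.9, locus gap 500 kb,
DEG adjusted-p 0.05, interaction score 0.4, top-100 centrality lists,
enrichment alpha 0.05 with > 3 overlap genes, >= 2 interaction sources with
>= 1 publication, and <= 10 very-common side effects for repurposing.

Configs load from a flat YAML document; unknown keys are rejected so typos
surface immediately.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ParameterError
from .synthio import DEG_TARGET_TISSUES, OBESITY_PHENOTYPES, TWAS_BRAIN_TISSUES

__all__ = ["PipelineConfig", "INPUT_FILES"]

#: Standard file names inside an input directory (as written by `simulate`).
INPUT_FILES = {
    "summary": "gwas_summary.tsv",
    "panel": "panel.vcf",
    "regulatory": "regulatory.tsv",
    "eqtl_links": "eqtl_links.tsv",
    "tissue_deg": "tissue_deg.tsv",
    "twas": "twas.tsv",
    "ppi_edges": "ppi_edges.tsv",
    "gene_sets": "gene_sets.gmt",
    "drug_gene": "drug_gene.tsv",
    "side_effects": "side_effects.tsv",
    "knockouts": "knockouts.tsv",
    "truth": "truth.json",
}


@dataclass
class PipelineConfig:
    input_dir: Path
    output_dir: Path
    seed: int = 0

    # stage thresholds (full-scale study defaults)
    p_sig: float = 1e-8
    window_bp: int = 500_000
    r2_min: float = 0.9
    locus_gap_bp: int = 500_000
    deg_alpha: float = 0.05
    score_min: float = 0.4
    top_k: int = 100
    enrich_alpha: float = 0.05
    min_overlap: int = 4
    min_sources: int = 2
    min_pmids: int = 1
    max_effects: int = 10
    n_trials: int = 10
    low_degree_max: int = 1
    test_method: str = "one-sample"

    deg_tissues: tuple[str, ...] = DEG_TARGET_TISSUES
    twas_phenotypes: tuple[str, ...] = OBESITY_PHENOTYPES
    twas_tissues: tuple[str, ...] = TWAS_BRAIN_TISSUES

    def __post_init__(self):
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.p_sig < 1.0:
            raise ParameterError(f"p_sig must be in (0, 1), got {self.p_sig}")
        if not 0.0 <= self.r2_min <= 1.0:
            raise ParameterError(f"r2_min must be in [0, 1], got {self.r2_min}")
        if not 0.0 <= self.score_min <= 1.0:
            raise ParameterError(f"score_min must be in [0, 1], got {self.score_min}")
        for name in ("window_bp", "locus_gap_bp", "top_k", "min_overlap"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        for name in ("deg_alpha", "enrich_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ParameterError(f"{name} must be in (0, 1), got {v}")
        for name in ("min_sources", "min_pmids", "max_effects", "low_degree_max"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.n_trials < 2:
            raise ParameterError("n_trials must be >= 2")
        if self.test_method not in ("one-sample", "prediction"):
            raise ParameterError(f"unknown test_method {self.test_method!r}")

    def input_path(self, key: str) -> Path:
        return self.input_dir / INPUT_FILES[key]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["input_dir"] = str(self.input_dir)
        d["output_dir"] = str(self.output_dir)
        for key in ("deg_tissues", "twas_phenotypes", "twas_tissues"):
            d[key] = list(d[key])
        return d

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("deg_tissues", "twas_phenotypes", "twas_tissues"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)
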