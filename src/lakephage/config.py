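"""Pipeline configuration.

The defaults reproduce the study's printed cutoffs exactly: candidate contigs
> 10 kb; dereplication at >= 95% mutual coverage with > 95%-identity hits at
e < 1e-3; CRISPR-spacer / shared-sequence linkage at >= 30 bp, >= 97%
identity, >= 97% query coverage, e <= 1e-5; fragment recruitment at > 95%
identity over >= 50 bp; presence at > 80% breadth; protein clustering at 30%
and 60% identity; translated-hit significance at e <= 1e-3.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0
    # discovery
    min_candidate_length_bp: int = 10_000
    min_terminal_overlap_bp: int = 20
    min_orf_length_aa: int = 30
    # dereplication
    derep_min_coverage: float = 0.95
    derep_min_hit_identity: float = 95.0
    derep_max_expectation: float = 1e-3
    # proteomic tree
    translated_max_expectation: float = 1e-3
    translated_matrix: str = "BLOSUM45"
    n_alternative_topologies: int = 100
    consensus_min_frequency: float = 0.5
    # host linkage
    spacer_min_length_bp: int = 30
    spacer_min_identity: float = 97.0
    spacer_min_query_coverage: float = 0.97
    spacer_max_expectation: float = 1e-5
    trna_min_overlap_bp: int = 20
    marker_min_identity: float = 30.0
    marker_min_coverage: float = 0.70
    marker_max_expectation: float = 1e-5
    # abundance
    recruit_min_identity: float = 95.0
    recruit_min_length_bp: int = 50
    presence_min_breadth: float = 0.80
    microbial_max_reads: int = 20_000_000
    # catalog
    protein_identity_levels: tuple = (30, 60)  # serialized as a list in YAML
    protein_min_coverage: float = 0.8
    # aligner
    nucleotide_seed_length: int = 13
    translated_seed_length: int = 4

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["protein_identity_levels"] = list(data["protein_identity_levels"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; valid keys: {sorted(valid)}"
            )
        if "protein_identity_levels" in data:
            data = dict(data)
            data["protein_identity_levels"] = tuple(data["protein_identity_levels"])
        return cls(**data)

    def override(self, **kw) -> "PipelineConfig":
        data = asdict(self)
        data.update({k: v for k, v in kw.items() if v is not None})
        return type(self).from_dict(data)
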