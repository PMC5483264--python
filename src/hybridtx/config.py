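"""Pipeline configuration: every numeric threshold in one place.

Defaults are the study conditions: NT/megaBLAST significance at E <= 1e-20,
NR/BLASTX at 1e-6, minimum transcript length 201 bases (products of 200
bases or shorter are discarded), splice junctions need >= 3 uniquely mapped
spliced reads, the low-coverage rule drops unspliced non-intronic
transcripts whose maximal per-base coverage is below 50x, translocations
need parts more than 2 Mb apart, proximal promoters are +-50 bases around
the dominant TSS, and 5'-completeness looks at the first 500 bases of the
first exon.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class PipelineConfig:
    evalue_nt: float = 1e-20
    evalue_nr: float = 1e-6
    min_pt_length: int = 201
    min_junction_support: int = 3
    cpb_threshold: int = 50
    translocation_distance: int = 2_000_000
    promoter_flank: int = 50
    first_exon_window: int = 500
    min_mapq: int = 0
    exon_share: str = "exact"  # or "overlap"
    junction_dialect: str = "native"  # or "star"

    def __post_init__(self) -> None:
        for name in (
            "evalue_nt", "evalue_nr", "min_pt_length", "cpb_threshold",
            "translocation_distance", "promoter_flank", "first_exon_window",
        ):
            if getattr(self, name) is None or getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.exon_share not in ("exact", "overlap"):
            raise ValueError(f"exon_share must be 'exact' or 'overlap', got {self.exon_share!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def as_dict(self) -> dict:
        return asdict(self)
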