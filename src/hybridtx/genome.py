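"""Genome sequences: FASTA-backed scaffold store and splice-site lookup."""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_ALPHABET = set("ACGTN")


@dataclass
class Genome:
    """Uppercase DNA scaffolds keyed by id."""

    scaffolds: dict[str, str]

    def __post_init__(self) -> None:
        for sid, seq in self.scaffolds.items():
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(f"scaffold {sid}: non-DNA characters {sorted(bad)}")

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self.scaffolds

    def length(self, scaffold_id: str) -> int:
        return len(self.scaffolds[scaffold_id])

    def fetch(self, scaffold_id: str, start: int, end: int) -> str:
        seq = self.scaffolds[scaffold_id]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"coordinates [{start}, {end}) out of bounds for scaffold "
                f"{scaffold_id} of length {len(seq)}"
            )
        return seq[start:end]

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        scaffolds: dict[str, str] = {}
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in scaffolds:
                raise ValueError(f"duplicate scaffold id {record.id}")
            scaffolds[record.id] = str(record.seq).upper()
        return cls(scaffolds)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=sid, description="")
            for sid, seq in self.scaffolds.items()
        ]
        SeqIO.write(records, str(path), "fasta")
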