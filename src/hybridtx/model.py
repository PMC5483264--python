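"""Core domain types for transcript models on a genome.

All coordinates are 0-based half-open on the forward genome strand; SAM
(1-based) and GTF (1-based inclusive) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

# mapping categories
UNIQUE = "unique"
MULTI = "multi"
TRANSLOCATION = "translocation"
UNMAPPED = "unmapped"

# splice status
SPLICED = "spliced"
UNSPLICED = "unspliced"
UNDETERMINED = "undetermined"

# strand symbols; "." = undetermined / not called
PLUS = "+"
MINUS = "-"
NO_STRAND = "."

Interval = tuple[int, int]


@dataclass(frozen=True)
class ExonChain:
    """An ordered exon chain of one transcript (or one part of one) on a scaffold.

    Exons are 0-based half-open, strictly increasing and non-overlapping.
    A chain with >= 2 exons is spliced; the gaps between consecutive exons
    are its introns.
    """

    pt_id: str
    scaffold: str
    strand: str  # "+", "-" or "."
    exons: tuple[Interval, ...]
    source: str = "denovo"  # denovo | genome_guided | isoseq | reference

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.pt_id}: exon chain must have >= 1 exon")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"{self.pt_id}: empty or inverted exon ({start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.pt_id}: exons overlap or are unsorted")
            prev_end = end

    @property
    def spliced(self) -> bool:
        return len(self.exons) >= 2

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate of the chain span."""
        return self.exons[0][0]

    @property
    def end(self) -> int:
        """Rightmost genomic coordinate (exclusive) of the chain span."""
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def exonic_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    def five_prime(self) -> int:
        """Genomic position of the 5' terminal base (strand-aware).

        Raises if the strand is undetermined.
        """
        if self.strand == PLUS:
            return self.start
        if self.strand == MINUS:
            return self.end - 1
        raise ValueError(f"{self.pt_id}: 5' terminus undefined without a strand")

    def first_exon(self) -> Interval:
        """The 5'-most exon (strand-aware)."""
        if self.strand == PLUS:
            return self.exons[0]
        if self.strand == MINUS:
            return self.exons[-1]
        raise ValueError(f"{self.pt_id}: first exon undefined without a strand")

    def with_strand(self, strand: str) -> "ExonChain":
        return ExonChain(self.pt_id, self.scaffold, strand, self.exons, self.source)


def extract_introns(chain: ExonChain) -> list[tuple[str, int, int]]:
    """Introns of a chain as (scaffold, start, end); empty for mono-exon chains."""
    return [(chain.scaffold, s, e) for s, e in chain.introns]


@dataclass
class TranscriptAlignment:
    """One putative transcript's placement on the genome.

    ``parts`` holds one ExonChain for unique/multi primaries and two for
    translocation-mapping transcripts; unmapped transcripts have none.
    """

    pt_id: str
    parts: list[ExonChain] = field(default_factory=list)
    mapping_category: str = UNMAPPED
    splice_status: str = UNDETERMINED
    source: str = "denovo"
    clipped: bool = False  # soft/hard clips were present at the termini

    @property
    def scaffold(self) -> str | None:
        return self.parts[0].scaffold if self.parts else None

    @property
    def spliced(self) -> bool:
        return self.splice_status == SPLICED

    @property
    def unspliced(self) -> bool:
        return self.splice_status == UNSPLICED

    def all_introns(self) -> list[tuple[str, int, int]]:
        out: list[tuple[str, int, int]] = []
        for part in self.parts:
            out.extend(extract_introns(part))
        return out

    @property
    def strand(self) -> str:
        strands = {p.strand for p in self.parts}
        if strands == {PLUS}:
            return PLUS
        if strands == {MINUS}:
            return MINUS
        return NO_STRAND


def classify_splice_status(aln: TranscriptAlignment) -> str:
    """Splice status from the mapping: N-derived introns in any part make a
    unique/translocation transcript spliced; multi-mapping or unmapped
    transcripts stay undetermined."""
    if aln.mapping_category in (MULTI, UNMAPPED):
        return UNDETERMINED
    if any(part.spliced for part in aln.parts):
        return SPLICED
    return UNSPLICED


def is_translocation_pair(parts: list[ExonChain], max_distance: int = 2_000_000) -> bool:
    """Two alignment parts on different scaffolds, or further apart than
    ``max_distance`` bases on one scaffold, constitute a translocation mapping."""
    if len(parts) != 2:
        return False
    a, b = parts
    if a.scaffold != b.scaffold:
        return True
    left, right = sorted((a, b), key=lambda c: c.start)
    return right.start - left.end > max_distance


def shares_intron_or_exon(a: ExonChain, b: ExonChain) -> bool:
    """True iff the two chains have a coordinate-identical intron or a
    coordinate-identical exon (both boundaries). Scaffold/strand agreement is
    the caller's responsibility."""
    if set(a.introns) & set(b.introns):
        return True
    return bool(set(a.exons) & set(b.exons))


def identical_junction_chain(a: ExonChain, b: ExonChain) -> bool:
    """Same ordered intron list (terminal exon boundaries free)."""
    return a.spliced and b.spliced and a.introns == b.introns


def identical_structure(a: ExonChain, b: ExonChain) -> bool:
    """Same ordered exon list including terminal coordinates."""
    return a.exons == b.exons


def span_overlap(a: ExonChain, b: ExonChain) -> int:
    """Overlap in bases between the genomic spans of two chains."""
    if a.scaffold != b.scaffold:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def iter_chains(alignments: list[TranscriptAlignment]) -> Iterator[ExonChain]:
    for aln in alignments:
        yield from aln.parts
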