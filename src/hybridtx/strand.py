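"""Sense-strand inference from splice-site consensus dinucleotides.

De novo assemblers report transcripts in arbitrary orientation, so the sense
strand of a spliced transcript is recovered from the genome: the canonical
intron boundary dinucleotides (GT-AG, the minor GC-AG and AT-AC) read in
forward-genome orientation imply a '+' intron, and their reverse complements
(CT-AC, CT-GC, GT-AT) imply a '-' intron. Each intron votes; the majority
wins and ties (or no recognizable consensus) leave the strand undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import Genome
from .model import MINUS, NO_STRAND, PLUS, ExonChain, TranscriptAlignment

# (donor, acceptor) dinucleotide pairs as read on the forward genome strand
PLUS_CONSENSI = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}
MINUS_CONSENSI = {("CT", "AC"), ("CT", "GC"), ("GT", "AT")}


@dataclass(frozen=True)
class SpliceSiteCall:
    """Donor/acceptor dinucleotides of one intron and the strand they imply."""

    scaffold: str
    start: int
    end: int
    donor_dinuc: str
    acceptor_dinuc: str
    implied_strand: str  # "+", "-" or "." when no consensus matches


def call_splice_site(genome: Genome, scaffold: str, start: int, end: int) -> SpliceSiteCall:
    """Look up the terminal dinucleotides of an intron on the forward genome."""
    if end - start < 4:
        raise ValueError(f"intron [{start}, {end}) on {scaffold} too short for splice sites")
    left = genome.fetch(scaffold, start, start + 2)
    right = genome.fetch(scaffold, end - 2, end)
    if (left, right) in PLUS_CONSENSI:
        implied = PLUS
    elif (left, right) in MINUS_CONSENSI:
        implied = MINUS
    else:
        implied = NO_STRAND
    return SpliceSiteCall(scaffold, start, end, left, right, implied)


def infer_sense_strand(chain: ExonChain, genome: Genome) -> str:
    """Majority vote over per-intron splice-site calls; ties or mono-exon
    chains give '.'."""
    return _vote(
        call_splice_site(genome, chain.scaffold, s, e) for s, e in chain.introns
    )


def infer_alignment_strand(aln: TranscriptAlignment, genome: Genome) -> str:
    """Strand vote pooled over all parts of a (possibly translocation) alignment."""
    return _vote(
        call_splice_site(genome, scaf, s, e) for scaf, s, e in aln.all_introns()
    )


def _vote(calls) -> str:
    plus = minus = 0
    for call in calls:
        if call.implied_strand == PLUS:
            plus += 1
        elif call.implied_strand == MINUS:
            minus += 1
    if plus > minus:
        return PLUS
    if minus > plus:
        return MINUS
    return NO_STRAND
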