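"""Parse spliced transcript-to-genome alignments from SAM/BAM.

Mapping categories follow the alignment record structure: a single primary
alignment is "unique"; secondary alignments at a distinct locus make the
transcript "multi"; a primary plus one supplementary part on different
scaffolds (or further than the translocation distance apart on one scaffold)
is a "translocation"; unmapped records give "unmapped". Exon blocks are the
reference spans of M/=/X/D runs split only at N runs, so a deletion stays
inside its exon and only an N opens an intron. Soft/hard clips never shift
exon boundaries; their presence is flagged per transcript.
"""

from __future__ import annotations

import logging

import pysam

from .model import (
    MULTI,
    TRANSLOCATION,
    UNIQUE,
    UNMAPPED,
    ExonChain,
    TranscriptAlignment,
    classify_splice_status,
    is_translocation_pair,
)

logger = logging.getLogger(__name__)

_REF_CONSUME_EXON = {0, 2, 7, 8}  # M, D, =, X
_INTRON = 3  # N
_CLIP = {4, 5}  # S, H


class AlignmentRecordError(ValueError):
    """A malformed alignment record, named after the offending transcript."""


def cigar_to_exons(reference_start: int, cigartuples) -> list[tuple[int, int]]:
    """Reference exon blocks (0-based half-open) of one alignment record."""
    exons: list[tuple[int, int]] = []
    pos = reference_start
    block_start = reference_start
    in_block = False
    for op, length in cigartuples:
        if length < 0:
            raise ValueError("negative CIGAR run length")
        if op in _REF_CONSUME_EXON:
            if not in_block:
                block_start = pos
                in_block = True
            pos += length
        elif op == _INTRON:
            if in_block:
                exons.append((block_start, pos))
                in_block = False
            pos += length
        # I, S, H, P: no reference advance
    if in_block:
        exons.append((block_start, pos))
    return exons


def _chain_from_record(rec: pysam.AlignedSegment, source: str) -> tuple[ExonChain, bool]:
    if rec.cigartuples is None:
        raise AlignmentRecordError(f"{rec.query_name}: mapped record without CIGAR")
    try:
        exons = cigar_to_exons(rec.reference_start, rec.cigartuples)
    except ValueError as exc:
        raise AlignmentRecordError(f"{rec.query_name}: malformed CIGAR ({exc})") from exc
    if not exons:
        raise AlignmentRecordError(f"{rec.query_name}: CIGAR consumes no reference bases")
    clipped = any(op in _CLIP for op, _ in rec.cigartuples)
    chain = ExonChain(
        pt_id=rec.query_name,
        scaffold=rec.reference_name,
        strand=".",
        exons=tuple(exons),
        source=source,
    )
    return chain, clipped


def parse_sam_alignments(
    sam_path,
    source: str = "denovo",
    translocation_distance: int = 2_000_000,
    min_length: int = 0,
) -> list[TranscriptAlignment]:
    """Read a transcript-to-genome SAM/BAM into classified TranscriptAlignments.

    Records are grouped by query name; one TranscriptAlignment is produced per
    query, in order of first appearance. Transcripts whose query sequence is
    shorter than ``min_length`` are dropped at ingest.
    """
    groups: dict[str, list[pysam.AlignedSegment]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            name = rec.query_name
            if name not in groups:
                groups[name] = []
                order.append(name)
            groups[name].append(rec)

    out: list[TranscriptAlignment] = []
    for name in order:
        recs = groups[name]
        if min_length:
            qlen = max((r.infer_read_length() or 0) for r in recs)
            if 0 < qlen < min_length:
                continue
        aln = _classify_group(name, recs, source, translocation_distance)
        aln.splice_status = classify_splice_status(aln)
        out.append(aln)
    return out


def _classify_group(
    name: str,
    recs: list[pysam.AlignedSegment],
    source: str,
    translocation_distance: int,
) -> TranscriptAlignment:
    mapped = [r for r in recs if not r.is_unmapped]
    if not mapped:
        return TranscriptAlignment(pt_id=name, parts=[], mapping_category=UNMAPPED, source=source)

    primary = [r for r in mapped if not r.is_secondary and not r.is_supplementary]
    supplementary = [r for r in mapped if r.is_supplementary]
    secondary = [r for r in mapped if r.is_secondary]

    chains_clips = [_chain_from_record(r, source) for r in primary + supplementary]
    parts = [c for c, _ in chains_clips]
    clipped = any(flag for _, flag in chains_clips)

    # secondaries at the primary locus are duplicates, not extra loci
    primary_loci = {(c.scaffold, c.start) for c in parts}
    distinct_secondary = [
        r for r in secondary
        if (r.reference_name, r.reference_start) not in primary_loci
    ]

    if distinct_secondary:
        category = MULTI
    elif len(parts) == 2 and is_translocation_pair(parts, translocation_distance):
        category = TRANSLOCATION
    elif len(parts) == 1:
        category = UNIQUE
    else:
        logger.warning(
            "%s: %d non-secondary alignment parts do not form a translocation; "
            "classified as multi-mapping", name, len(parts),
        )
        category = MULTI

    if category == MULTI:
        # keep the primary part only, for reporting; splice status is undetermined
        parts = parts[:1]
    return TranscriptAlignment(
        pt_id=name,
        parts=parts,
        mapping_category=category,
        source=source,
        clipped=clipped,
    )
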