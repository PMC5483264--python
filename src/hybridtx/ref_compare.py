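"""Comparison of integrated transcripts to a reference transcript set.

Each spliced, uniquely mapping, stranded transcript is related to the
reference as identical_junctions (equal ordered intron chain on the same
strand), shared_gene (shares at least one coordinate-identical intron or
exon) or novel. For non-novel transcripts the maximally overlapping
reference (by exonic-base overlap, same strand) anchors a strand-aware
terminus comparison, and gene identifiers are transferred from every
reference the transcript shares a feature with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import ExonChain

IDENTICAL_JUNCTIONS = "identical_junctions"
SHARED_GENE = "shared_gene"
NOVEL = "novel"

BOTH_LONGER = "both_longer"
LONGER_3_ONLY = "longer_3_only"
LONGER_5_ONLY = "longer_5_only"
BOTH_SHORTER = "both_shorter"
MIXED_OR_EQUAL = "mixed_or_equal"
TERMINUS_NA = "NA"


@dataclass
class RefComparisonRecord:
    pt_id: str
    relation: str = NOVEL
    best_ref_id: str | None = None
    terminus_class: str = TERMINUS_NA
    transferred_gene_ids: list[str] = field(default_factory=list)


def _shared_intron_count(a: ExonChain, b: ExonChain) -> int:
    return len(set(a.introns) & set(b.introns))


def exonic_overlap(a: ExonChain, b: ExonChain) -> int:
    """Total overlapping exonic bases between two chains on one scaffold."""
    if a.scaffold != b.scaffold:
        return 0
    total = 0
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def maximal_overlap_ref(pt: ExonChain, refs: list[ExonChain]) -> str | None:
    """Reference maximizing exonic-base overlap with the transcript (same
    strand); ties broken by shared-intron count (desc) then ref id (asc)."""
    best: tuple[int, int, str] | None = None
    for ref in refs:
        if ref.scaffold != pt.scaffold or ref.strand != pt.strand:
            continue
        ov = exonic_overlap(pt, ref)
        if ov <= 0:
            continue
        key = (-ov, -_shared_intron_count(pt, ref), ref.pt_id)
        if best is None or key < best:
            best = key
    return best[2] if best else None


def classify_termini(pt: ExonChain, ref: ExonChain) -> str:
    """Strand-aware terminus comparison; "longer" is strict genomic extension."""
    if pt.strand == "+":
        longer5 = pt.start < ref.start
        longer3 = pt.end > ref.end
        shorter5 = pt.start > ref.start
        shorter3 = pt.end < ref.end
    elif pt.strand == "-":
        longer5 = pt.end > ref.end
        longer3 = pt.start < ref.start
        shorter5 = pt.end < ref.end
        shorter3 = pt.start > ref.start
    else:
        raise ValueError(f"{pt.pt_id}: terminus comparison requires a strand")
    if longer5 and longer3:
        return BOTH_LONGER
    if longer3 and not longer5:
        return LONGER_3_ONLY
    if longer5 and not longer3:
        return LONGER_5_ONLY
    if shorter5 and shorter3:
        return BOTH_SHORTER
    return MIXED_OR_EQUAL


def compare_to_reference(
    pts: list[ExonChain],
    refs: list[ExonChain],
    ref_gene_ids: dict[str, str] | None = None,
) -> dict[str, RefComparisonRecord]:
    """Relate every transcript to the reference set.

    ``ref_gene_ids`` maps reference transcript ids to gene identifiers for
    gene-ID transfer; when absent the reference transcript id itself is
    transferred.
    """
    refs = [r for r in refs if r.spliced and r.strand in "+-"]
    chain_index: dict[tuple, list[ExonChain]] = {}
    feature_index: dict[tuple, list[ExonChain]] = {}
    by_scaffold_strand: dict[tuple[str, str], list[ExonChain]] = {}
    for ref in refs:
        chain_index.setdefault((ref.scaffold, ref.strand, ref.introns), []).append(ref)
        for s, e in ref.introns:
            feature_index.setdefault((ref.scaffold, ref.strand, "i", s, e), []).append(ref)
        for s, e in ref.exons:
            feature_index.setdefault((ref.scaffold, ref.strand, "e", s, e), []).append(ref)
        by_scaffold_strand.setdefault((ref.scaffold, ref.strand), []).append(ref)

    records = {}
    for pt in pts:
        rec = RefComparisonRecord(pt_id=pt.pt_id)
        sharing: dict[str, ExonChain] = {}
        for s, e in pt.introns:
            for ref in feature_index.get((pt.scaffold, pt.strand, "i", s, e), []):
                sharing[ref.pt_id] = ref
        for s, e in pt.exons:
            for ref in feature_index.get((pt.scaffold, pt.strand, "e", s, e), []):
                sharing[ref.pt_id] = ref
        if (pt.scaffold, pt.strand, pt.introns) in chain_index:
            rec.relation = IDENTICAL_JUNCTIONS
        elif sharing:
            rec.relation = SHARED_GENE
        if rec.relation != NOVEL:
            candidates = by_scaffold_strand.get((pt.scaffold, pt.strand), [])
            rec.best_ref_id = maximal_overlap_ref(pt, candidates)
            if rec.best_ref_id is not None:
                best = next(r for r in candidates if r.pt_id == rec.best_ref_id)
                rec.terminus_class = classify_termini(pt, best)
            rec.transferred_gene_ids = transfer_gene_ids_for(pt, sharing, ref_gene_ids)
        records[pt.pt_id] = rec
    return records


def transfer_gene_ids_for(
    pt: ExonChain,
    sharing_refs: dict[str, ExonChain],
    ref_gene_ids: dict[str, str] | None,
) -> list[str]:
    ids = {
        (ref_gene_ids or {}).get(ref_id, ref_id) for ref_id in sharing_refs
    }
    return sorted(ids)


def transfer_gene_ids(
    pts: list[ExonChain],
    refs: list[ExonChain],
    ref_gene_ids: dict[str, str] | None = None,
) -> dict[str, list[str]]:
    """Gene identifiers inherited by each transcript from every reference it
    shares an intron or exon with (same strand); novel transcripts get []."""
    records = compare_to_reference(pts, refs, ref_gene_ids)
    return {pt_id: rec.transferred_gene_ids for pt_id, rec in records.items()}
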