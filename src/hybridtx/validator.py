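"""Structure validation against IsoSeq long reads and CAGE promoters.

A spliced, uniquely mapping transcript is fully validated when its ordered
intron chain equals that of at least one same-strand IsoSeq full-length read
(terminal exon boundaries are free to differ); it is partially validated
when it shares at least one intron or exon with an IsoSeq read. 5'-end
completeness uses CAGE-derived proximal promoters (the dominant TSS of each
cluster flanked by 50 bases): a transcript is 5'-complete when a same-strand
promoter overlaps its first exon, restricted to the 5'-most 500 bases of
that exon when the exon is longer.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .model import ExonChain, shares_intron_or_exon

ISOSEQ_FULL = "full"
ISOSEQ_PARTIAL = "partial"
ISOSEQ_NONE = "none"


@dataclass(frozen=True)
class PromoterInterval:
    scaffold: str
    start: int
    end: int
    strand: str
    dominant_tss: int
    source: str = "pig_macrophage"


@dataclass
class ValidationRecord:
    pt_id: str
    isoseq_status: str = ISOSEQ_NONE
    n_supporting_isoseq: int = 0
    cage_complete_5p: bool = False
    promoter_distance: int | None = None


def validate_with_isoseq(
    pts: list[ExonChain], isoseq_chains: list[ExonChain]
) -> dict[str, ValidationRecord]:
    """Per-transcript IsoSeq support: full (identical junction chain),
    partial (shared intron or exon), or none. All comparisons are same
    scaffold and strand."""
    chain_index: dict[tuple, int] = {}
    feature_index: dict[tuple, bool] = {}
    for iso in isoseq_chains:
        if not iso.spliced or iso.strand not in "+-":
            continue
        key = (iso.scaffold, iso.strand, iso.introns)
        chain_index[key] = chain_index.get(key, 0) + 1
        for s, e in iso.introns:
            feature_index[(iso.scaffold, iso.strand, "i", s, e)] = True
        for s, e in iso.exons:
            feature_index[(iso.scaffold, iso.strand, "e", s, e)] = True

    records = {}
    for pt in pts:
        rec = ValidationRecord(pt_id=pt.pt_id)
        n_full = chain_index.get((pt.scaffold, pt.strand, pt.introns), 0)
        if n_full:
            rec.isoseq_status = ISOSEQ_FULL
            rec.n_supporting_isoseq = n_full
        else:
            shared = any(
                (pt.scaffold, pt.strand, "i", s, e) in feature_index for s, e in pt.introns
            ) or any(
                (pt.scaffold, pt.strand, "e", s, e) in feature_index for s, e in pt.exons
            )
            if shared:
                rec.isoseq_status = ISOSEQ_PARTIAL
        records[pt.pt_id] = rec
    return records


def read_tss_clusters(path) -> pd.DataFrame:
    """TSS cluster table: scaffold, start, end, strand, dominant_tss
    (0-based), optional source column."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"scaffold", "start", "end", "strand", "dominant_tss"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TSS cluster table missing columns: {sorted(missing)}")
    return df


def build_promoters(
    tss_clusters: pd.DataFrame,
    flank: int = 50,
    scaffold_lengths: dict[str, int] | None = None,
) -> list[PromoterInterval]:
    """Proximal promoters: +-``flank`` bases around each dominant TSS,
    clipped to scaffold bounds."""
    promoters = []
    for row in tss_clusters.itertuples(index=False):
        tss = int(row.dominant_tss)
        scaffold = str(row.scaffold)
        if scaffold_lengths is not None:
            slen = scaffold_lengths[scaffold]
            if not 0 <= tss < slen:
                raise ValueError(f"dominant TSS {tss} outside scaffold {scaffold} [0, {slen})")
        else:
            slen = None
        start = max(0, tss - flank)
        end = tss + flank + 1 if slen is None else min(slen, tss + flank + 1)
        promoters.append(
            PromoterInterval(
                scaffold=scaffold,
                start=start,
                end=end,
                strand=str(row.strand),
                dominant_tss=tss,
                source=str(getattr(row, "source", "pig_macrophage")),
            )
        )
    return promoters


def write_promoters_bed(path, promoters: list[PromoterInterval]) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(promoters):
            fh.write(f"{p.scaffold}\t{p.start}\t{p.end}\tpromoter_{i + 1}\t0\t{p.strand}\n")


def promoter_distance(pt: ExonChain, promoters: list[PromoterInterval]) -> int | None:
    """Signed gap from the transcript's 5' terminus to the nearest same-strand
    promoter: 0 when the terminus lies inside a promoter, positive when the
    nearest promoter is upstream (5') of the terminus, negative when it is
    downstream. None when no same-strand promoter exists on the scaffold."""
    terminus = pt.five_prime()
    best: int | None = None
    for p in promoters:
        if p.scaffold != pt.scaffold or p.strand != pt.strand:
            continue
        if p.start <= terminus < p.end:
            gap, upstream = 0, True
        elif terminus >= p.end:  # promoter left of the terminus
            gap, upstream = terminus - p.end, pt.strand == "+"
        else:  # promoter right of the terminus
            gap, upstream = p.start - terminus, pt.strand == "-"
        signed = gap if upstream else -gap
        if best is None or abs(signed) < abs(best):
            best = signed
    return best


def five_prime_complete(
    pt: ExonChain,
    promoters: list[PromoterInterval],
    first_exon_window: int = 500,
    trees: dict[tuple[str, str], IntervalTree] | None = None,
) -> bool:
    """True iff a same-strand promoter overlaps the 5'-most
    ``first_exon_window`` bases of the first exon (the whole exon when it is
    not longer than the window)."""
    fe_start, fe_end = pt.first_exon()
    if fe_end - fe_start > first_exon_window:
        if pt.strand == "+":
            fe_end = fe_start + first_exon_window
        else:
            fe_start = fe_end - first_exon_window
    if trees is not None:
        tree = trees.get((pt.scaffold, pt.strand))
        return tree is not None and bool(tree.overlap(fe_start, fe_end))
    return any(
        p.scaffold == pt.scaffold
        and p.strand == pt.strand
        and p.start < fe_end
        and p.end > fe_start
        for p in promoters
    )


def promoter_trees(promoters: list[PromoterInterval]) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for p in promoters:
        trees.setdefault((p.scaffold, p.strand), IntervalTree()).addi(p.start, p.end)
    return trees


def validate_transcripts(
    pts: list[ExonChain],
    isoseq_chains: list[ExonChain],
    promoters: list[PromoterInterval],
    first_exon_window: int = 500,
) -> dict[str, ValidationRecord]:
    """IsoSeq and CAGE validation combined into one record per transcript."""
    records = validate_with_isoseq(pts, isoseq_chains)
    trees = promoter_trees(promoters)
    for pt in pts:
        rec = records[pt.pt_id]
        rec.cage_complete_5p = five_prime_complete(pt, promoters, first_exon_window, trees)
        rec.promoter_distance = promoter_distance(pt, promoters)
    return records
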