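"""Transcriptional-noise filtering primitives.

An intron-interval catalog built from three evidence sources (spliced de
novo transcripts, spliced genome-guided transcripts, and splice junctions
supported by enough uniquely mapped spliced reads) defines what "intronic"
means; mono-exon transcripts overlapping any cataloged intron by at least
one base are intronic noise candidates. Per-base coverage (CPB) from the
read alignments drives the low-coverage rule: an unspliced non-intronic
transcript whose span never reaches the coverage threshold is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .alignments import cigar_to_exons
from .model import ExonChain, TranscriptAlignment

DENOVO_SPLICED = "denovo_spliced"
GG_SPLICED = "gg_spliced"
JUNCTION_READS = "junction_reads"

INTRONIC = "intronic"
NON_INTRONIC = "non_intronic"

KEEP = "keep"
DROP = "drop"


@dataclass
class IntronCatalog:
    """Evidence-tagged intron intervals keyed by (scaffold, start, end)."""

    evidence: dict[tuple[str, int, int], set[str]] = field(default_factory=dict)
    read_support: dict[tuple[str, int, int], int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.evidence)

    def __contains__(self, interval: tuple[str, int, int]) -> bool:
        return interval in self.evidence

    def intervals(self) -> list[tuple[str, int, int]]:
        return sorted(self.evidence)

    def trees(self) -> dict[str, IntervalTree]:
        """Per-scaffold interval trees for overlap queries."""
        by_scaffold: dict[str, IntervalTree] = {}
        for scaffold, start, end in self.evidence:
            by_scaffold.setdefault(scaffold, IntervalTree()).addi(start, end)
        return by_scaffold


def build_intron_catalog(
    denovo_spliced: list[ExonChain] | list[TranscriptAlignment],
    gg_spliced: list[ExonChain] | list[TranscriptAlignment],
    junctions: list[tuple[tuple[str, int, int], int]] | None = None,
    min_support: int = 3,
) -> IntronCatalog:
    """Union of intron intervals from both assemblies plus read-supported
    junctions with support >= ``min_support``; identical intervals merge their
    evidence tags."""
    catalog = IntronCatalog()
    for tag, chains in ((DENOVO_SPLICED, denovo_spliced), (GG_SPLICED, gg_spliced)):
        for item in chains:
            introns = (
                item.all_introns()
                if isinstance(item, TranscriptAlignment)
                else [(item.scaffold, s, e) for s, e in item.introns]
            )
            for interval in introns:
                catalog.evidence.setdefault(interval, set()).add(tag)
    for interval, support in junctions or []:
        if support < 0:
            raise ValueError(f"negative junction support for {interval}")
        if support >= min_support:
            catalog.evidence.setdefault(interval, set()).add(JUNCTION_READS)
            catalog.read_support[interval] = max(
                support, catalog.read_support.get(interval, 0)
            )
    return catalog


def read_junction_tsv(path, dialect: str = "native") -> list[tuple[tuple[str, int, int], int]]:
    """Junction evidence from TSV.

    ``native``: columns scaffold, intron_start, intron_end, support with
    0-based half-open coordinates. ``star``: STAR SJ.out.tab (1-based
    inclusive intron; column 7 is the unique-read support), converted.
    """
    if dialect == "native":
        df = pd.read_csv(path, sep="\t", comment="#")
        return [
            ((row.scaffold, int(row.intron_start), int(row.intron_end)), int(row.support))
            for row in df.itertuples()
        ]
    if dialect == "star":
        # chrom, intron start/end (1-based inclusive), strand, motif,
        # annotated, unique reads, multi reads, max overhang
        df = pd.read_csv(path, sep="\t", header=None)
        return [
            ((str(row[0]), int(row[1]) - 1, int(row[2])), int(row[6]))
            for row in df.itertuples(index=False)
        ]
    raise ValueError(f"unknown junction dialect {dialect!r}")


def classify_unspliced(pt: ExonChain, catalog: IntronCatalog, trees=None) -> str:
    """intronic iff the mono-exon transcript overlaps any cataloged intron by
    >= 1 base on its scaffold (strand-agnostic)."""
    if pt.spliced:
        raise ValueError(f"{pt.pt_id}: intronic classification applies to mono-exon PTs")
    trees = trees if trees is not None else catalog.trees()
    tree = trees.get(pt.scaffold)
    if tree is not None and tree.overlap(pt.start, pt.end):
        return INTRONIC
    return NON_INTRONIC


@dataclass
class CoverageTrack:
    """Per-scaffold per-base read depth."""

    depth: dict[str, np.ndarray] = field(default_factory=dict)

    def max_over(self, scaffold: str, start: int, end: int) -> int:
        arr = self.depth.get(scaffold)
        if arr is None:
            return 0
        window = arr[max(start, 0): min(end, len(arr))]
        return int(window.max()) if window.size else 0

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for scaffold in sorted(self.depth):
                arr = self.depth[scaffold]
                # run-length encode constant-depth stretches
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for s, e in zip(starts, ends):
                    d = int(arr[s])
                    if d > 0:
                        fh.write(f"{scaffold}\t{s}\t{e}\t{d}\n")

    @classmethod
    def from_bedgraph(cls, path, scaffold_lengths: dict[str, int]) -> "CoverageTrack":
        track = cls({s: np.zeros(n, dtype=np.int64) for s, n in scaffold_lengths.items()})
        df = pd.read_csv(path, sep="\t", header=None, names=["scaffold", "start", "end", "depth"])
        for row in df.itertuples(index=False):
            track.depth[row.scaffold][int(row.start): int(row.end)] = int(row.depth)
        return track


def compute_cpb(
    read_sam_path,
    scaffold_lengths: dict[str, int],
    min_mapq: int = 0,
) -> CoverageTrack:
    """Per-base coverage from primary read alignments, split (N-aware): the
    intron gap of a spliced read contributes no depth."""
    deltas = {s: np.zeros(n + 1, dtype=np.int64) for s, n in scaffold_lengths.items()}
    with pysam.AlignmentFile(str(read_sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if rec.reference_name not in deltas:
                raise ValueError(f"read {rec.query_name} on unknown scaffold {rec.reference_name}")
            delta = deltas[rec.reference_name]
            for start, end in cigar_to_exons(rec.reference_start, rec.cigartuples):
                if end > len(delta) - 1:
                    raise ValueError(
                        f"read {rec.query_name} extends past the end of {rec.reference_name}"
                    )
                delta[start] += 1
                delta[end] -= 1
    return CoverageTrack({s: np.cumsum(d[:-1]) for s, d in deltas.items()})


def low_coverage_filter(pt: ExonChain, track: CoverageTrack, threshold: int = 50) -> str:
    """drop iff the maximal CPB over the transcript's genomic span is strictly
    below ``threshold``."""
    return KEEP if track.max_over(pt.scaffold, pt.start, pt.end) >= threshold else DROP
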