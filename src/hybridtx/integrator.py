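"""Filter cascade and assembly integration.

The ordered five-stage cascade removes, in this order: (i) mitochondrial
top-hit transcripts, (ii) unspliced intronic transcripts, (iii) non-vertebrate
contaminants without a better genome alignment, (iv) unspliced non-intronic
transcripts in low-coverage regions, and (v) multi-mapping/unmapped
transcripts without RNA-like top hits. A transcript is attributed to the
FIRST stage that removes it, so the per-stage counts always sum to
input - output.

Integration merges the filtered de novo and genome-guided sets into five
disjoint components: (A) all de novo spliced transcripts; (B) genome-guided
spliced transcripts with no same-strand shared intron/exon partner in A;
(C) de novo unspliced non-intronic transcripts; (D) genome-guided unspliced
non-intronic transcripts with no strand-agnostic overlap with C; and (E)
multi-mapping/unmapped de novo transcripts with RNA-like top hits.
Transcripts on one strand sharing at least one intron or exon are clustered
into gene loci (connected components of the sharing relation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
from intervaltree import IntervalTree

from .homology import RNA_BIOTYPES, TopHitAnnotation, flag_contaminant, flag_mitochondrial
from .model import MULTI, UNMAPPED, ExonChain, TranscriptAlignment
from .noise import INTRONIC, NON_INTRONIC, CoverageTrack

logger = logging.getLogger(__name__)

STAGE_MITO = "mitochondrial"
STAGE_INTRONIC = "unspliced_intronic"
STAGE_CONTAMINANT = "contaminant"
STAGE_LOWCOV = "lowcov_nonintronic"
STAGE_UNANCHORED = "unanchored"


@dataclass
class FilterReport:
    """Per-stage removal bookkeeping; first-match attribution."""

    input_n: int = 0
    removed_mito: int = 0
    removed_unspliced_intronic: int = 0
    removed_contaminant: int = 0
    removed_lowcov_nonintronic: int = 0
    removed_unanchored: int = 0
    output_n: int = 0
    removed: dict[str, str] = field(default_factory=dict)  # pt_id -> stage

    def total_removed(self) -> int:
        return (
            self.removed_mito
            + self.removed_unspliced_intronic
            + self.removed_contaminant
            + self.removed_lowcov_nonintronic
            + self.removed_unanchored
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "input_n": self.input_n,
            "removed_mito": self.removed_mito,
            "removed_unspliced_intronic": self.removed_unspliced_intronic,
            "removed_contaminant": self.removed_contaminant,
            "removed_lowcov_nonintronic": self.removed_lowcov_nonintronic,
            "removed_unanchored": self.removed_unanchored,
            "output_n": self.output_n,
        }


def apply_filter_cascade(
    pts: list[TranscriptAlignment],
    tophits: dict[str, TopHitAnnotation],
    noise_labels: dict[str, str],
    coverage: CoverageTrack,
    genome_scores: dict[str, float] | None = None,
    cpb_threshold: int = 50,
) -> tuple[list[TranscriptAlignment], FilterReport]:
    """Apply the ordered five-stage filter; returns kept transcripts and the
    stage-attributed report.

    ``noise_labels`` must label every unspliced uniquely/translocation-mapping
    transcript as intronic or non-intronic. ``genome_scores`` carries the best
    genome alignment score per transcript for the contaminant "unless" clause.
    """
    genome_scores = genome_scores or {}
    report = FilterReport(input_n=len(pts))
    kept: list[TranscriptAlignment] = []
    no_hit = TopHitAnnotation(pt_id="", is_significant=False)

    for aln in pts:
        top = tophits.get(aln.pt_id, no_hit)
        label = noise_labels.get(aln.pt_id)
        if aln.unspliced and label not in (INTRONIC, NON_INTRONIC):
            raise RuntimeError(
                f"{aln.pt_id}: unspliced transcript without an intronic/non-intronic "
                "label; noise classification must run before the cascade"
            )
        if flag_mitochondrial(top):
            report.removed_mito += 1
            report.removed[aln.pt_id] = STAGE_MITO
        elif aln.unspliced and label == INTRONIC:
            report.removed_unspliced_intronic += 1
            report.removed[aln.pt_id] = STAGE_INTRONIC
        elif flag_contaminant(top, genome_scores.get(aln.pt_id)):
            report.removed_contaminant += 1
            report.removed[aln.pt_id] = STAGE_CONTAMINANT
        elif aln.unspliced and label == NON_INTRONIC and _max_cpb(aln, coverage) < cpb_threshold:
            report.removed_lowcov_nonintronic += 1
            report.removed[aln.pt_id] = STAGE_LOWCOV
        elif aln.mapping_category in (MULTI, UNMAPPED) and (
            not top.is_significant or top.biotype not in RNA_BIOTYPES
        ):
            report.removed_unanchored += 1
            report.removed[aln.pt_id] = STAGE_UNANCHORED
        else:
            kept.append(aln)

    report.output_n = len(kept)
    assert report.input_n == report.output_n + report.total_removed()
    return kept, report


def _max_cpb(aln: TranscriptAlignment, coverage: CoverageTrack) -> int:
    return max(
        (coverage.max_over(p.scaffold, p.start, p.end) for p in aln.parts), default=0
    )


# ---------------------------------------------------------------------------
# integration

COMPONENT_NAMES = {
    "A": "denovo_spliced",
    "B": "gg_spliced_unique",
    "C": "denovo_unspliced_nonintronic",
    "D": "gg_unspliced_nonoverlapping",
    "E": "denovo_multi_or_unmapped_rna",
}


@dataclass
class IntegratedTranscriptome:
    components: dict[str, list[TranscriptAlignment]]

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.components.values())

    def provenance(self) -> dict[str, str]:
        return {
            aln.pt_id: comp
            for comp, members in self.components.items()
            for aln in members
        }

    def component_sizes(self) -> dict[str, int]:
        return {comp: len(members) for comp, members in self.components.items()}

    def all_members(self) -> list[TranscriptAlignment]:
        return [aln for comp in "ABCDE" for aln in self.components[comp]]


def _feature_keys(chain: ExonChain, exon_share: str):
    """Hashable shared-feature keys: introns and (in exact mode) exons."""
    keys = [("i", s, e) for s, e in chain.introns]
    if exon_share == "exact":
        keys.extend(("e", s, e) for s, e in chain.exons)
    return keys


def integrate(
    denovo_kept: list[TranscriptAlignment],
    gg_kept: list[TranscriptAlignment],
    exon_share: str = "exact",
) -> IntegratedTranscriptome:
    """Merge two filtered assemblies into the five-component transcriptome."""
    comp: dict[str, list[TranscriptAlignment]] = {k: [] for k in "ABCDE"}
    for aln in denovo_kept:
        if aln.mapping_category in (MULTI, UNMAPPED):
            comp["E"].append(aln)
        elif aln.spliced:
            comp["A"].append(aln)
        else:
            comp["C"].append(aln)

    # same-strand shared-feature index over stranded A members
    keys_index: dict[tuple, bool] = {}
    exon_trees: dict[tuple[str, str], IntervalTree] = {}
    for aln in comp["A"]:
        for part in aln.parts:
            if part.strand not in "+-":
                continue  # strand-undetermined de novo spliced PTs do not block B
            for key in _feature_keys(part, exon_share):
                keys_index[(part.scaffold, part.strand, *key)] = True
            if exon_share == "overlap":
                tree = exon_trees.setdefault((part.scaffold, part.strand), IntervalTree())
                for s, e in part.exons:
                    tree.addi(s, e)

    c_trees: dict[str, IntervalTree] = {}
    for aln in comp["C"]:
        for part in aln.parts:
            c_trees.setdefault(part.scaffold, IntervalTree()).addi(part.start, part.end)

    for aln in gg_kept:
        if aln.spliced:
            part = aln.parts[0]
            if part.strand not in "+-":
                logger.warning(
                    "%s: spliced genome-guided PT without a strand call; "
                    "excluded from component B", aln.pt_id,
                )
                continue
            keyed = any(
                (part.scaffold, part.strand, *key) in keys_index
                for key in _feature_keys(part, exon_share)
            )
            if not keyed and exon_share == "overlap":
                tree = exon_trees.get((part.scaffold, part.strand))
                keyed = tree is not None and any(tree.overlap(s, e) for s, e in part.exons)
            if not keyed:
                comp["B"].append(aln)
        else:
            part = aln.parts[0]
            tree = c_trees.get(part.scaffold)
            if tree is None or not tree.overlap(part.start, part.end):
                comp["D"].append(aln)
    return IntegratedTranscriptome(comp)


# ---------------------------------------------------------------------------
# gene clustering


@dataclass
class GeneLocus:
    locus_id: str
    pt_ids: list[str]
    scaffold: str
    strand: str
    start: int
    end: int
    gene_symbols: list[str] = field(default_factory=list)


def cluster_genes(chains: list[ExonChain]) -> list[GeneLocus]:
    """Connected components of the shared-intron/exon relation per
    (scaffold, strand); the locus span is the union of member spans."""
    graph = nx.Graph()
    feature_owner: dict[tuple, str] = {}
    by_id: dict[str, ExonChain] = {}
    for chain in chains:
        if chain.strand not in "+-":
            raise ValueError(f"{chain.pt_id}: gene clustering requires a strand call")
        if chain.pt_id in by_id:
            raise ValueError(f"duplicate pt_id {chain.pt_id} in gene clustering")
        by_id[chain.pt_id] = chain
        graph.add_node(chain.pt_id)
        for key in _feature_keys(chain, "exact"):
            full = (chain.scaffold, chain.strand, *key)
            if full in feature_owner:
                graph.add_edge(feature_owner[full], chain.pt_id)
            else:
                feature_owner[full] = chain.pt_id

    loci = []
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    for idx, members in enumerate(components):
        rep = by_id[members[0]]
        loci.append(
            GeneLocus(
                locus_id=f"PG{idx + 1:05d}",
                pt_ids=members,
                scaffold=rep.scaffold,
                strand=rep.strand,
                start=min(by_id[m].start for m in members),
                end=max(by_id[m].end for m in members),
            )
        )
    return loci
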