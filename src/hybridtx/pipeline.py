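"""Pipeline orchestration over a state directory.

Each stage reads its inputs (raw files or artifacts of earlier stages) from
disk and writes its artifacts back, so the stages can run as one call
(:func:`run_pipeline`) or individually in order with identical results.
Every summary count is recomputed from the per-transcript tables, never
tallied independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .alignments import parse_sam_alignments
from .config import PipelineConfig
from .genome import Genome
from .gtfio import read_gtf_chains, read_gtf_gene_ids, write_gtf_alignments, write_gtf_chains
from .homology import read_blast_tsv, read_subject_meta, select_top_hit
from .integrator import (
    FilterReport,
    IntegratedTranscriptome,
    apply_filter_cascade,
    cluster_genes,
    integrate,
)
from .model import (
    MULTI,
    TRANSLOCATION,
    UNIQUE,
    UNMAPPED,
    ExonChain,
    TranscriptAlignment,
)
from .noise import (
    CoverageTrack,
    build_intron_catalog,
    classify_unspliced,
    compute_cpb,
    read_junction_tsv,
)
from .ref_compare import compare_to_reference
from .strand import infer_alignment_strand
from .validator import build_promoters, read_tss_clusters, validate_transcripts


@dataclass
class PipelineInputs:
    """Paths to the raw pipeline inputs."""

    genome_fasta: str
    pt_sam: str
    gg_gtf: str
    reads_sam: str
    junction_tsv: str
    blast_tsv: str
    subject_meta_tsv: str
    cage_tsv: str
    isoseq_gtf: str
    reference_gtf: str
    genome_scores_tsv: str | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineInputs":
        data = {k: v for k, v in data.items() if k != "truth_tsv"}
        return cls(**data)

    def as_dict(self) -> dict:
        out = {
            name: getattr(self, name)
            for name in (
                "genome_fasta", "pt_sam", "gg_gtf", "reads_sam", "junction_tsv",
                "blast_tsv", "subject_meta_tsv", "cage_tsv", "isoseq_gtf",
                "reference_gtf",
            )
        }
        if self.genome_scores_tsv:
            out["genome_scores_tsv"] = self.genome_scores_tsv
        return out

    def check(self) -> None:
        for name, value in self.as_dict().items():
            if value and not Path(value).exists():
                raise FileNotFoundError(f"pipeline input {name}: {value} does not exist")


# ---------------------------------------------------------------------------
# alignment-table (de)serialization


def _encode_exons(exons) -> str:
    return ";".join(f"{s}-{e}" for s, e in exons)


def _decode_exons(text: str) -> tuple[tuple[int, int], ...]:
    if not text:
        return ()
    return tuple(tuple(map(int, pair.split("-"))) for pair in text.split(";"))


def write_alignment_table(path, alignments: list[TranscriptAlignment]) -> None:
    rows = []
    for aln in alignments:
        if not aln.parts:
            rows.append((aln.pt_id, aln.mapping_category, aln.splice_status,
                         aln.source, aln.clipped, 0, "", "", ""))
        for idx, part in enumerate(aln.parts):
            rows.append((aln.pt_id, aln.mapping_category, aln.splice_status,
                         aln.source, aln.clipped, idx, part.scaffold, part.strand,
                         _encode_exons(part.exons)))
    pd.DataFrame(
        rows,
        columns=["pt_id", "mapping_category", "splice_status", "source", "clipped",
                 "part", "scaffold", "strand", "exons"],
    ).to_csv(path, sep="\t", index=False)


def read_alignment_table(path) -> list[TranscriptAlignment]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"exons": str})
    out: dict[str, TranscriptAlignment] = {}
    for row in df.itertuples(index=False):
        aln = out.get(row.pt_id)
        if aln is None:
            aln = TranscriptAlignment(
                pt_id=str(row.pt_id),
                parts=[],
                mapping_category=row.mapping_category,
                splice_status=row.splice_status,
                source=row.source,
                clipped=bool(row.clipped),
            )
            out[str(row.pt_id)] = aln
        if row.scaffold:
            aln.parts.append(
                ExonChain(str(row.pt_id), str(row.scaffold), str(row.strand) or ".",
                          _decode_exons(row.exons), row.source)
            )
    return list(out.values())


# ---------------------------------------------------------------------------
# stages


def stage_classify(config: PipelineConfig, inputs: PipelineInputs, outdir: Path):
    """Parse and classify both assemblies; call sense strands for spliced
    de novo transcripts from the splice-site consensus."""
    outdir.mkdir(parents=True, exist_ok=True)
    genome = Genome.from_fasta(inputs.genome_fasta)
    denovo = parse_sam_alignments(
        inputs.pt_sam,
        source="denovo",
        translocation_distance=config.translocation_distance,
        min_length=config.min_pt_length,
    )
    for aln in denovo:
        if aln.spliced:
            strand = infer_alignment_strand(aln, genome)
            aln.parts = [p.with_strand(strand) for p in aln.parts]

    gg_chains = read_gtf_chains(inputs.gg_gtf, source="genome_guided")
    gg = []
    for chain in gg_chains:
        aln = TranscriptAlignment(
            pt_id=chain.pt_id,
            parts=[chain],
            mapping_category=UNIQUE,
            splice_status="spliced" if chain.spliced else "unspliced",
            source="genome_guided",
        )
        gg.append(aln)

    write_alignment_table(outdir / "denovo_alignments.tsv", denovo)
    write_alignment_table(outdir / "gg_alignments.tsv", gg)
    write_gtf_alignments(outdir / "denovo_classified.gtf",
                         [a for a in denovo if a.parts])
    write_gtf_alignments(outdir / "gg_classified.gtf", gg)
    return denovo, gg


def _scaffold_lengths(genome_fasta) -> dict[str, int]:
    genome = Genome.from_fasta(genome_fasta)
    return {sid: len(seq) for sid, seq in genome.scaffolds.items()}


def stage_filter(config: PipelineConfig, inputs: PipelineInputs, outdir: Path):
    """Build the intron catalog, label unspliced transcripts, compute CPB,
    annotate top hits and run the five-stage cascade on both assemblies."""
    denovo = read_alignment_table(outdir / "denovo_alignments.tsv")
    gg = read_alignment_table(outdir / "gg_alignments.tsv")

    denovo_spliced = [a for a in denovo
                      if a.spliced and a.mapping_category in (UNIQUE, TRANSLOCATION)]
    gg_spliced = [a for a in gg if a.spliced]
    junctions = read_junction_tsv(inputs.junction_tsv, dialect=config.junction_dialect)
    catalog = build_intron_catalog(
        denovo_spliced, gg_spliced, junctions, min_support=config.min_junction_support
    )
    pd.DataFrame(
        [(s, a, b, ",".join(sorted(catalog.evidence[(s, a, b)])),
          catalog.read_support.get((s, a, b), 0))
         for s, a, b in catalog.intervals()],
        columns=["scaffold", "start", "end", "evidence", "read_support"],
    ).to_csv(outdir / "intron_catalog.tsv", sep="\t", index=False)

    trees = catalog.trees()
    noise_labels: dict[str, str] = {}
    for aln in denovo + gg:
        if aln.unspliced and aln.parts:
            noise_labels[aln.pt_id] = classify_unspliced(aln.parts[0], catalog, trees)
    pd.DataFrame(sorted(noise_labels.items()), columns=["pt_id", "label"]).to_csv(
        outdir / "noise_labels.tsv", sep="\t", index=False
    )

    coverage = compute_cpb(
        inputs.reads_sam, _scaffold_lengths(inputs.genome_fasta), min_mapq=config.min_mapq
    )
    coverage.to_bedgraph(outdir / "coverage.bedgraph")

    hits = read_blast_tsv(inputs.blast_tsv)
    meta = read_subject_meta(inputs.subject_meta_tsv)
    tophits = {
        pt_id: select_top_hit(pt_hits, meta, evalue_cutoff=config.evalue_nt)
        for pt_id, pt_hits in hits.items()
    }
    pd.DataFrame(
        [(t.pt_id, t.is_significant, t.top_subject or "", t.evalue, t.bitscore,
          t.species_class or "", t.biotype or "")
         for t in sorted(tophits.values(), key=lambda t: t.pt_id)],
        columns=["pt_id", "is_significant", "top_subject", "evalue", "bitscore",
                 "species_class", "biotype"],
    ).to_csv(outdir / "tophits.tsv", sep="\t", index=False)

    genome_scores: dict[str, float] = {}
    if inputs.genome_scores_tsv:
        gs = pd.read_csv(inputs.genome_scores_tsv, sep="\t")
        genome_scores = dict(zip(gs.pt_id, gs.score))

    reports = {}
    for name, pts in (("denovo", denovo), ("gg", gg)):
        kept, report = apply_filter_cascade(
            pts, tophits, noise_labels, coverage,
            genome_scores=genome_scores, cpb_threshold=config.cpb_threshold,
        )
        reports[name] = report
        pd.DataFrame(report.as_dict().items(), columns=["stage", "count"]).to_csv(
            outdir / f"filter_report_{name}.tsv", sep="\t", index=False
        )
        write_alignment_table(outdir / f"kept_{name}.tsv", kept)
        _write_removed_bed(outdir / f"removed_{name}.bed", pts, report)
    return reports


def _write_removed_bed(path, pts, report: FilterReport) -> None:
    with open(path, "w") as fh:
        for aln in pts:
            reason = report.removed.get(aln.pt_id)
            if reason is None:
                continue
            if aln.parts:
                for part in aln.parts:
                    fh.write(f"{part.scaffold}\t{part.start}\t{part.end}\t"
                             f"{aln.pt_id}\t0\t{part.strand}\t{reason}\n")
            else:
                fh.write(f".\t0\t0\t{aln.pt_id}\t0\t.\t{reason}\n")


def stage_integrate(config: PipelineConfig, outdir: Path) -> IntegratedTranscriptome:
    """Merge the two filtered assemblies and cluster gene loci."""
    denovo_kept = read_alignment_table(outdir / "kept_denovo.tsv")
    gg_kept = read_alignment_table(outdir / "kept_gg.tsv")
    integrated = integrate(denovo_kept, gg_kept, exon_share=config.exon_share)

    provenance = integrated.provenance()
    pd.DataFrame(sorted(provenance.items()), columns=["pt_id", "component"]).to_csv(
        outdir / "provenance.tsv", sep="\t", index=False
    )
    members = integrated.all_members()
    write_alignment_table(outdir / "integrated_alignments.tsv", members)
    write_gtf_alignments(outdir / "integrated.gtf", [a for a in members if a.parts])

    stranded_spliced = [
        a.parts[0]
        for a in members
        if a.spliced and a.mapping_category == UNIQUE and a.parts[0].strand in "+-"
    ]
    loci = cluster_genes(stranded_spliced)
    pd.DataFrame(
        [(l.locus_id, l.scaffold, l.strand, l.start, l.end, ",".join(l.pt_ids))
         for l in loci],
        columns=["locus_id", "scaffold", "strand", "start", "end", "pt_ids"],
    ).to_csv(outdir / "gene_loci.tsv", sep="\t", index=False)
    return integrated


def _comparable_chains(outdir: Path) -> list[ExonChain]:
    """Spliced, uniquely mapping, stranded transcripts of the integrated set."""
    members = read_alignment_table(outdir / "integrated_alignments.tsv")
    return [
        a.parts[0]
        for a in members
        if a.spliced and a.mapping_category == UNIQUE and a.parts[0].strand in "+-"
    ]


def stage_validate(config: PipelineConfig, inputs: PipelineInputs, outdir: Path):
    """IsoSeq junction validation and CAGE 5'-completeness."""
    pts = _comparable_chains(outdir)
    isoseq = read_gtf_chains(inputs.isoseq_gtf, source="isoseq")
    clusters = read_tss_clusters(inputs.cage_tsv)
    promoters = build_promoters(
        clusters, flank=config.promoter_flank,
        scaffold_lengths=_scaffold_lengths(inputs.genome_fasta),
    )
    records = validate_transcripts(
        pts, isoseq, promoters, first_exon_window=config.first_exon_window
    )
    pd.DataFrame(
        [(r.pt_id, r.isoseq_status, r.n_supporting_isoseq, r.cage_complete_5p,
          "" if r.promoter_distance is None else r.promoter_distance)
         for r in sorted(records.values(), key=lambda r: r.pt_id)],
        columns=["pt_id", "isoseq_status", "n_supporting_isoseq",
                 "cage_complete_5p", "promoter_distance"],
    ).to_csv(outdir / "validation.tsv", sep="\t", index=False)
    return records


def stage_compare(config: PipelineConfig, inputs: PipelineInputs, outdir: Path):
    """Relate integrated transcripts to the reference annotation."""
    pts = _comparable_chains(outdir)
    refs = read_gtf_chains(inputs.reference_gtf, source="reference")
    gene_ids = read_gtf_gene_ids(inputs.reference_gtf)
    records = compare_to_reference(pts, refs, gene_ids)
    pd.DataFrame(
        [(r.pt_id, r.relation, r.best_ref_id or "", r.terminus_class,
          ",".join(r.transferred_gene_ids))
         for r in sorted(records.values(), key=lambda r: r.pt_id)],
        columns=["pt_id", "relation", "best_ref_id", "terminus_class",
                 "transferred_gene_ids"],
    ).to_csv(outdir / "ref_comparison.tsv", sep="\t", index=False)

    novel = [pt for pt in pts if records[pt.pt_id].relation == "novel"]
    write_gtf_chains(outdir / "novel_pts.gtf", novel)
    return records


def summarize_counts(outdir: Path) -> dict:
    """Aggregate the flowchart counts from the per-transcript tables."""
    summary: dict = {}
    for name in ("denovo", "gg"):
        report = pd.read_csv(outdir / f"filter_report_{name}.tsv", sep="\t")
        summary[f"filter_{name}"] = dict(zip(report.stage, report["count"].astype(int)))

    prov = pd.read_csv(outdir / "provenance.tsv", sep="\t")
    comp_sizes = prov.groupby("component").size().to_dict()
    summary["components"] = {k: int(comp_sizes.get(k, 0)) for k in "ABCDE"}
    summary["integrated_total"] = int(len(prov))

    catalog = pd.read_csv(outdir / "intron_catalog.tsv", sep="\t")
    summary["intron_catalog_n"] = int(len(catalog))

    labels = pd.read_csv(outdir / "noise_labels.tsv", sep="\t")
    summary["unspliced_labels"] = {
        k: int(v) for k, v in labels.groupby("label").size().items()
    }

    loci = pd.read_csv(outdir / "gene_loci.tsv", sep="\t")
    summary["gene_loci_n"] = int(len(loci))

    validation = pd.read_csv(outdir / "validation.tsv", sep="\t")
    summary["isoseq_status"] = {
        k: int(v) for k, v in validation.groupby("isoseq_status").size().items()
    }
    summary["cage_complete_n"] = int(validation.cage_complete_5p.sum())

    comparison = pd.read_csv(outdir / "ref_comparison.tsv", sep="\t")
    summary["ref_relation"] = {
        k: int(v) for k, v in comparison.groupby("relation").size().items()
    }
    summary["terminus_classes"] = {
        k: int(v) for k, v in comparison.groupby("terminus_class").size().items()
    }
    return summary


def stage_report(config: PipelineConfig, outdir: Path) -> dict:
    summary = summarize_counts(outdir)
    summary["config"] = config.as_dict()
    with open(outdir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    rows = []

    def flatten(prefix, obj):
        if isinstance(obj, dict):
            for k, v in sorted(obj.items()):
                flatten(f"{prefix}.{k}" if prefix else str(k), v)
        else:
            rows.append((prefix, obj))

    flatten("", {k: v for k, v in summary.items() if k != "config"})
    pd.DataFrame(rows, columns=["count", "value"]).to_csv(
        outdir / "report.tsv", sep="\t", index=False
    )
    return summary


def run_pipeline(
    config: PipelineConfig,
    inputs: PipelineInputs,
    outdir,
) -> dict:
    """classify -> filter -> integrate -> validate -> compare -> report."""
    inputs.check()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_classify(config, inputs, outdir)
    stage_filter(config, inputs, outdir)
    stage_integrate(config, outdir)
    stage_validate(config, inputs, outdir)
    stage_compare(config, inputs, outdir)
    return stage_report(config, outdir)
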