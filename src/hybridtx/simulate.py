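"""Deterministic synthetic data emulating every pipeline input.

A small multi-scaffold genome is generated with planted multi-isoform gene
models whose introns carry canonical splice-site dinucleotides (GT-AG on the
forward strand for '+' genes, their reverse complements for '-' genes).
Around the gene models, every noise class the filter cascade targets is
planted by construction: intronic mono-exon fragments, low-coverage
non-intronic fragments, non-vertebrate contaminants, mitochondrial-hit
transcripts, translocation mappings, multi-mappers, and unanchored
multi/unmapped transcripts, together with genome-guided duplicates and
genome-guided-only transcripts, CAGE TSS clusters at planted promoters,
IsoSeq-like full-length chains, and a reference annotation. Every emitted
transcript has exactly one truth row, so every pipeline decision can be
checked against construction rather than against another implementation.

Coverage is planted exactly: "high-coverage islands" are tiled by 55 stacked
reads and "low-coverage islands" by 49, one below the 50x threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genome import Genome
from .model import ExonChain

BASES = np.array(list("ACGT"))

# truth classes
CLEAN_SPLICED = "clean_spliced"
NOVEL_VS_REF = "novel_vs_ref"
INTRONIC_FRAGMENT = "intronic_fragment"
LOWCOV_FRAGMENT = "lowcov_fragment"
UNSPLICED_KEEP = "unspliced_keep"
CONTAMINANT = "contaminant"
MITOCHONDRIAL = "mitochondrial"
TRANSLOCATION_T = "translocation"
MULTI_MAPPER = "multi_mapper"
UNANCHORED = "unanchored"
GG_DUPLICATE = "gg_duplicate"
GG_UNIQUE = "gg_unique"
GG_INTRONIC = "gg_intronic"
GG_UNSPLICED_KEEP = "gg_unspliced_keep"
GG_UNSPLICED_DUP = "gg_unspliced_dup"

# expected integration outcome per truth class (None = filtered out / excluded)
EXPECTED_COMPONENT = {
    CLEAN_SPLICED: "A",
    NOVEL_VS_REF: "A",
    TRANSLOCATION_T: "A",
    GG_UNIQUE: "B",
    UNSPLICED_KEEP: "C",
    GG_UNSPLICED_KEEP: "D",
    MULTI_MAPPER: "E",
    INTRONIC_FRAGMENT: None,
    LOWCOV_FRAGMENT: None,
    CONTAMINANT: None,
    MITOCHONDRIAL: None,
    UNANCHORED: None,
    GG_DUPLICATE: None,
    GG_INTRONIC: None,
    GG_UNSPLICED_DUP: None,
}

# expected cascade removal stage per truth class (None = survives its cascade)
EXPECTED_STAGE = {
    MITOCHONDRIAL: "mitochondrial",
    INTRONIC_FRAGMENT: "unspliced_intronic",
    GG_INTRONIC: "unspliced_intronic",
    CONTAMINANT: "contaminant",
    LOWCOV_FRAGMENT: "lowcov_nonintronic",
    UNANCHORED: "unanchored",
}


class ConfigError(ValueError):
    """Infeasible generator configuration."""


@dataclass
class GeneratorConfig:
    n_scaffolds: int = 3
    scaffold_length: int = 100_000
    # gene roles
    n_genes_full: int = 6        # de novo clean, ref trimmed, IsoSeq full, CAGE at TSS
    n_genes_truncated: int = 2   # de novo PT starts at exon 2; ref + IsoSeq full-length
    n_genes_novel: int = 2       # de novo clean, absent from the reference
    n_genes_gg_only: int = 2     # spliced PTs only in the genome-guided assembly
    # noise / component counts
    n_intronic: int = 6
    n_gg_intronic: int = 2
    n_lowcov: int = 4
    n_unspliced_keep: int = 3
    n_gg_unspliced_keep: int = 2
    n_gg_unspliced_dup: int = 2
    n_gg_duplicate: int = 4
    n_contaminant: int = 3
    n_mito: int = 2
    n_translocation: int = 2
    n_multi: int = 2
    n_unanchored: int = 2
    # coverage depths: one above and one just below the 50x rule
    highcov_depth: int = 55
    lowcov_depth: int = 49
    minor_splice_fraction: float = 0.0  # fraction of gene introns using GC-AG

    @property
    def n_genes(self) -> int:
        return (
            self.n_genes_full + self.n_genes_truncated
            + self.n_genes_novel + self.n_genes_gg_only
        )

    def validate(self) -> None:
        slots = self.n_scaffolds * _slots_per_scaffold(self.scaffold_length)
        if self.n_genes > slots:
            raise ConfigError(
                f"{self.n_genes} genes do not fit in {slots} gene slots; "
                "increase scaffold_length or n_scaffolds"
            )
        if self.n_intronic > 0 and self.n_genes_full == 0:
            raise ConfigError("intronic fragments need full gene models with introns")
        if self.n_gg_intronic > 0 and self.n_genes_full == 0:
            raise ConfigError("gg intronic fragments need full gene models with introns")
        if self.n_gg_duplicate > self.n_genes_full:
            raise ConfigError("n_gg_duplicate cannot exceed n_genes_full")
        if self.n_gg_unspliced_dup > self.n_unspliced_keep:
            raise ConfigError("n_gg_unspliced_dup cannot exceed n_unspliced_keep")
        if self.n_translocation > 0 and self.n_scaffolds < 2:
            raise ConfigError("translocations need at least two scaffolds")
        if not 0 <= self.minor_splice_fraction <= 1:
            raise ConfigError("minor_splice_fraction must be in [0, 1]")
        n_islands = self.n_unspliced_keep + self.n_gg_unspliced_keep
        if n_islands + self.n_lowcov + self.n_mito > self.n_scaffolds * 16:
            raise ConfigError("too many coverage islands for the scaffold layout")


# gene body layout, relative to the gene start
_EXON_REL = ((0, 300), (800, 1050), (1700, 2100))
_GENE_SPAN = 2100
_GENE_SLOT = 9000
_GENE_BASE = 3000
_ISLAND_LEN = 400
_HIGHCOV_BASE = 60_000
_LOWCOV_BASE = 80_000
_ISLAND_STEP = 1200
_TRANS_BASE = 50_000
_MULTI_BASE = 55_000


def _slots_per_scaffold(scaffold_length: int) -> int:
    usable = min(scaffold_length, _TRANS_BASE - 2000) - _GENE_BASE - _GENE_SPAN
    return max(0, usable // _GENE_SLOT + 1)


@dataclass
class GeneModel:
    gene_id: str
    scaffold: str
    strand: str
    start: int
    role: str

    @property
    def exons(self) -> tuple[tuple[int, int], ...]:
        return tuple((self.start + s, self.start + e) for s, e in _EXON_REL)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        ex = self.exons
        return tuple((ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1))

    @property
    def end(self) -> int:
        return self.start + _GENE_SPAN

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def chain(self, pt_id: str, source: str, strand: str | None = None) -> ExonChain:
        return ExonChain(pt_id, self.scaffold, strand or self.strand, self.exons, source)


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def build_genome(config: GeneratorConfig, rng: np.random.Generator):
    """Random genome with planted gene models; returns (Genome, genes)."""
    config.validate()
    scaffold_ids = [f"s{i + 1}" for i in range(config.n_scaffolds)]
    seqs = {
        sid: rng.choice(BASES, size=config.scaffold_length)
        for sid in scaffold_ids
    }

    roles = (
        ["full"] * config.n_genes_full
        + ["truncated"] * config.n_genes_truncated
        + ["novel"] * config.n_genes_novel
        + ["gg_only"] * config.n_genes_gg_only
    )
    genes: list[GeneModel] = []
    for g, role in enumerate(roles):
        scaffold = scaffold_ids[g % config.n_scaffolds]
        slot = g // config.n_scaffolds
        start = _GENE_BASE + slot * _GENE_SLOT
        strand = "+" if g % 2 == 0 else "-"
        gene = GeneModel(f"GENE{g + 1:02d}", scaffold, strand, start, role)
        genes.append(gene)
        for j, (istart, iend) in enumerate(gene.introns):
            donor, acceptor = ("GT", "AG")
            if config.minor_splice_fraction and rng.random() < config.minor_splice_fraction:
                donor, acceptor = ("GC", "AG")
            if strand == "-":
                donor, acceptor = _revcomp(acceptor), _revcomp(donor)
            seq = seqs[scaffold]
            seq[istart], seq[istart + 1] = donor[0], donor[1]
            seq[iend - 2], seq[iend - 1] = acceptor[0], acceptor[1]

    # translocation spliced parts carry their own planted GT-AG intron
    for t in range(config.n_translocation):
        scaffold = scaffold_ids[t % config.n_scaffolds]
        p = _TRANS_BASE + (t // config.n_scaffolds) * 1500
        seq = seqs[scaffold]
        istart, iend = p + 150, p + 650
        seq[istart], seq[istart + 1] = "G", "T"
        seq[iend - 2], seq[iend - 1] = "A", "G"

    genome = Genome({sid: "".join(seqs[sid]) for sid in scaffold_ids})
    return genome, genes


def generate_genome(seed: int, n_scaffolds: int = 3, scaffold_length: int = 100_000,
                    path=None) -> Genome:
    """Reproducible genome with planted gene models; optionally written to FASTA."""
    config = GeneratorConfig(n_scaffolds=n_scaffolds, scaffold_length=scaffold_length)
    genome, _ = build_genome(config, np.random.default_rng(seed))
    if path is not None:
        genome.to_fasta(path)
    return genome


# ---------------------------------------------------------------------------
# input file emission


def _sam_header(genome: Genome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [
                {"SN": sid, "LN": len(seq)}
                for sid, seq in genome.scaffolds.items()
            ],
        }
    )


def _segment(header, name, scaffold, pos, cigar, flag=0) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.flag = flag
    if scaffold is not None:
        seg.reference_id = header.get_tid(scaffold)
        seg.reference_start = pos
        seg.cigarstring = cigar
        seg.mapping_quality = 60
    return seg


def _gene_cigar(exons) -> str:
    parts = []
    for i, (s, e) in enumerate(exons):
        if i:
            parts.append(f"{s - exons[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


@dataclass
class SyntheticDataset:
    """Paths of all emitted inputs plus the per-PT truth table."""

    genome_fasta: Path
    pt_sam: Path
    gg_gtf: Path
    reads_sam: Path
    junction_tsv: Path
    blast_tsv: Path
    subject_meta_tsv: Path
    cage_tsv: Path
    isoseq_gtf: Path
    reference_gtf: Path
    truth_tsv: Path
    genes: list[GeneModel] = field(default_factory=list)

    @property
    def truth(self) -> pd.DataFrame:
        return pd.read_csv(self.truth_tsv, sep="\t")

    def paths(self) -> dict[str, str]:
        return {
            name: str(getattr(self, name))
            for name in (
                "genome_fasta", "pt_sam", "gg_gtf", "reads_sam", "junction_tsv",
                "blast_tsv", "subject_meta_tsv", "cage_tsv", "isoseq_gtf",
                "reference_gtf", "truth_tsv",
            )
        }


def generate_inputs(
    seed: int,
    outdir,
    config: GeneratorConfig | None = None,
) -> SyntheticDataset:
    """Emit every pipeline input plus the truth table into ``outdir``."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome, genes = build_genome(config, rng)
    header = _sam_header(genome)
    scaffold_ids = list(genome.scaffolds)
    truth_rows: list[dict] = []

    def record_truth(pt_id, assembly, true_class, strand=".", gene="", full_length=False):
        truth_rows.append(
            {
                "pt_id": pt_id,
                "assembly": assembly,
                "true_class": true_class,
                "true_strand": strand,
                "true_gene": gene,
                "full_length_flag": full_length,
            }
        )

    # ---------------- de novo PT SAM -------------------------------------
    pt_sam = outdir / "denovo_pts.sam"
    blast_rows: list[tuple] = []
    _hsp = dict(pident=98.0, length=300, mismatch=5, gapopen=0,
                qstart=1, qend=300, sstart=1, send=300)

    def blast_row(qid, sid, evalue, bitscore):
        blast_rows.append(
            (qid, sid, _hsp["pident"], _hsp["length"], _hsp["mismatch"],
             _hsp["gapopen"], _hsp["qstart"], _hsp["qend"], _hsp["sstart"],
             _hsp["send"], evalue, bitscore)
        )

    full_genes = [g for g in genes if g.role == "full"]
    truncated_genes = [g for g in genes if g.role == "truncated"]
    novel_genes = [g for g in genes if g.role == "novel"]
    gg_only_genes = [g for g in genes if g.role == "gg_only"]

    with pysam.AlignmentFile(str(pt_sam), "w", header=header) as sam:
        # clean spliced PTs: full, truncated, and novel genes
        for g in full_genes:
            pid = f"pt_clean_{g.gene_id}"
            sam.write(_segment(header, pid, g.scaffold, g.start, _gene_cigar(g.exons)))
            record_truth(pid, "denovo", CLEAN_SPLICED, g.strand, g.gene_id, True)
            blast_row(pid, "pig_mrna_1", 1e-80, 500.0)
        for g in truncated_genes:
            pid = f"pt_trunc_{g.gene_id}"
            # missing the 5'-most exon: '+' genes lose the first exon,
            # '-' genes lose the last one
            exons = g.exons[1:] if g.strand == "+" else g.exons[:-1]
            sam.write(_segment(header, pid, g.scaffold, exons[0][0], _gene_cigar(exons)))
            record_truth(pid, "denovo", CLEAN_SPLICED, g.strand, g.gene_id, False)
            blast_row(pid, "pig_mrna_1", 1e-80, 500.0)
        for g in novel_genes:
            pid = f"pt_novel_{g.gene_id}"
            sam.write(_segment(header, pid, g.scaffold, g.start, _gene_cigar(g.exons)))
            record_truth(pid, "denovo", NOVEL_VS_REF, g.strand, g.gene_id, True)
            blast_row(pid, "pig_mrna_1", 1e-80, 500.0)

        # intronic fragments: mono-exon PTs inside intron 1 of full genes
        for k in range(config.n_intronic):
            g = full_genes[k % len(full_genes)]
            istart, _ = g.introns[0]
            pos = istart + 20 + 30 * (k // len(full_genes))
            pid = f"pt_intronic_{k + 1}"
            sam.write(_segment(header, pid, g.scaffold, pos, "250M"))
            record_truth(pid, "denovo", INTRONIC_FRAGMENT, ".", g.gene_id)

        # coverage islands
        n_keep_islands = config.n_unspliced_keep + config.n_gg_unspliced_keep

        def island(base, j):
            scaffold = scaffold_ids[j % len(scaffold_ids)]
            start = base + (j // len(scaffold_ids)) * _ISLAND_STEP
            return scaffold, start

        for k in range(config.n_unspliced_keep):
            scaffold, start = island(_HIGHCOV_BASE, k)
            pid = f"pt_keep_{k + 1}"
            sam.write(_segment(header, pid, scaffold, start + 50, "300M"))
            record_truth(pid, "denovo", UNSPLICED_KEEP)
            blast_row(pid, "pig_mrna_1", 1e-60, 400.0)
        for k in range(config.n_lowcov):
            scaffold, start = island(_LOWCOV_BASE, k)
            pid = f"pt_lowcov_{k + 1}"
            sam.write(_segment(header, pid, scaffold, start + 50, "300M"))
            record_truth(pid, "denovo", LOWCOV_FRAGMENT)
        for k in range(config.n_mito):
            scaffold, start = island(_LOWCOV_BASE, config.n_lowcov + k)
            pid = f"pt_mito_{k + 1}"
            sam.write(_segment(header, pid, scaffold, start + 50, "300M"))
            record_truth(pid, "denovo", MITOCHONDRIAL)
            blast_row(pid, "pig_mito_1", 1e-90, 600.0)

        # contaminants: unmapped, non-vertebrate top hits
        for k in range(config.n_contaminant):
            pid = f"pt_contam_{k + 1}"
            sam.write(_segment(header, pid, None, 0, None, flag=4))
            record_truth(pid, "denovo", CONTAMINANT)
            blast_row(pid, "nonvert_1", 1e-40, 300.0)

        # translocations: spliced part + distant unspliced part
        for t in range(config.n_translocation):
            pid = f"pt_transloc_{t + 1}"
            scaffold = scaffold_ids[t % len(scaffold_ids)]
            other = scaffold_ids[(t + 1) % len(scaffold_ids)]
            p = _TRANS_BASE + (t // len(scaffold_ids)) * 1500
            sam.write(_segment(header, pid, scaffold, p, "150M500N150M"))
            sam.write(_segment(header, pid, other, p, "120M", flag=2048))
            record_truth(pid, "denovo", TRANSLOCATION_T, "+", f"trans_{t + 1}")
            blast_row(pid, "pig_mrna_1", 1e-70, 450.0)

        # multi-mappers with RNA top hits (kept at stage v)
        multi_scaffold = scaffold_ids[-1]
        for m in range(config.n_multi):
            pid = f"pt_multi_{m + 1}"
            sam.write(_segment(header, pid, multi_scaffold, _MULTI_BASE + m * 800, "250M"))
            sam.write(
                _segment(header, pid, multi_scaffold, _MULTI_BASE + 2500 + m * 800,
                         "250M", flag=256)
            )
            record_truth(pid, "denovo", MULTI_MAPPER)
            blast_row(pid, "pig_ncrna_1", 1e-50, 350.0)

        # unanchored: one unmapped PT without a significant hit, then multi
        # PTs with genomic-DNA top hits
        for u in range(config.n_unanchored):
            pid = f"pt_unanchored_{u + 1}"
            if u == 0:
                sam.write(_segment(header, pid, None, 0, None, flag=4))
                blast_row(pid, "weak_1", 1e-5, 40.0)  # below the 1e-20 cutoff
            else:
                pos = _MULTI_BASE + 1600 + u * 800
                sam.write(_segment(header, pid, multi_scaffold, pos, "250M"))
                sam.write(
                    _segment(header, pid, multi_scaffold, pos + 4000, "250M", flag=256)
                )
                blast_row(pid, "pig_gdna_1", 1e-40, 300.0)
            record_truth(pid, "denovo", UNANCHORED)

    # ---------------- genome-guided GTF ----------------------------------
    gg_gtf = outdir / "genome_guided.gtf"
    gg_lines: list[str] = []

    def gg_feature(tid, scaffold, strand, exons):
        for s, e in exons:
            attrs = f'gene_id "{tid}"; transcript_id "{tid}";'
            gg_lines.append(
                f"{scaffold}\tCufflinks\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}"
            )

    for k in range(config.n_gg_duplicate):
        g = full_genes[k]
        tid = f"gg_dup_{g.gene_id}"
        gg_feature(tid, g.scaffold, g.strand, g.exons)
        record_truth(tid, "gg", GG_DUPLICATE, g.strand, g.gene_id, True)
        blast_row(tid, "pig_mrna_1", 1e-70, 450.0)
    for g in gg_only_genes:
        tid = f"gg_unique_{g.gene_id}"
        gg_feature(tid, g.scaffold, g.strand, g.exons)
        record_truth(tid, "gg", GG_UNIQUE, g.strand, g.gene_id, True)
        blast_row(tid, "pig_mrna_1", 1e-70, 450.0)
    for k in range(config.n_gg_intronic):
        g = full_genes[k % len(full_genes)]
        istart, _ = g.introns[1]
        pos = istart + 30 + 40 * (k // len(full_genes))
        tid = f"gg_intronic_{k + 1}"
        gg_feature(tid, g.scaffold, ".", ((pos, pos + 250),))
        record_truth(tid, "gg", GG_INTRONIC, ".", g.gene_id)
    for k in range(config.n_gg_unspliced_keep):
        scaffold = scaffold_ids[(config.n_unspliced_keep + k) % len(scaffold_ids)]
        start = (
            _HIGHCOV_BASE
            + ((config.n_unspliced_keep + k) // len(scaffold_ids)) * _ISLAND_STEP
        )
        tid = f"gg_keep_{k + 1}"
        gg_feature(tid, scaffold, ".", ((start + 40, start + 340),))
        record_truth(tid, "gg", GG_UNSPLICED_KEEP)
        blast_row(tid, "pig_mrna_1", 1e-50, 380.0)
    for k in range(config.n_gg_unspliced_dup):
        scaffold = scaffold_ids[k % len(scaffold_ids)]
        start = _HIGHCOV_BASE + (k // len(scaffold_ids)) * _ISLAND_STEP
        tid = f"gg_usdup_{k + 1}"
        gg_feature(tid, scaffold, ".", ((start + 100, start + 380),))
        record_truth(tid, "gg", GG_UNSPLICED_DUP)
        blast_row(tid, "pig_mrna_1", 1e-50, 380.0)
    gg_gtf.write_text("\n".join(gg_lines) + "\n")

    # ---------------- coverage reads SAM ----------------------------------
    reads_sam = outdir / "reads.sam"
    with pysam.AlignmentFile(str(reads_sam), "w", header=header) as sam:
        read_n = 0
        for j in range(n_keep_islands):
            scaffold = scaffold_ids[j % len(scaffold_ids)]
            start = _HIGHCOV_BASE + (j // len(scaffold_ids)) * _ISLAND_STEP
            for _ in range(config.highcov_depth):
                read_n += 1
                sam.write(_segment(header, f"read_{read_n}", scaffold, start,
                                   f"{_ISLAND_LEN}M"))
        for j in range(config.n_lowcov + config.n_mito):
            scaffold = scaffold_ids[j % len(scaffold_ids)]
            start = _LOWCOV_BASE + (j // len(scaffold_ids)) * _ISLAND_STEP
            for _ in range(config.lowcov_depth):
                read_n += 1
                sam.write(_segment(header, f"read_{read_n}", scaffold, start,
                                   f"{_ISLAND_LEN}M"))

    # ---------------- junction evidence TSV -------------------------------
    junction_tsv = outdir / "junctions.tsv"
    jrows = []
    for g in genes:
        if g.role == "gg_only":
            continue  # those introns enter the catalog via the gg assembly only
        for s, e in g.introns:
            jrows.append((g.scaffold, s, e, 10))
    # a junction-only intron (no assembled transcript) and a below-support decoy
    jrows.append((scaffold_ids[min(1, len(scaffold_ids) - 1)], 95_000, 95_400, 5))
    jrows.append((scaffold_ids[0], 95_000, 95_500, 2))
    pd.DataFrame(jrows, columns=["scaffold", "intron_start", "intron_end", "support"]).to_csv(
        junction_tsv, sep="\t", index=False
    )

    # ---------------- BLAST tabular + subject metadata --------------------
    blast_tsv = outdir / "blast_nt.tsv"
    pd.DataFrame(blast_rows).to_csv(blast_tsv, sep="\t", index=False, header=False)
    subject_meta_tsv = outdir / "subject_meta.tsv"
    pd.DataFrame(
        [
            ("pig_mrna_1", "pig", "mRNA_cDNA", 2000),
            ("pig_ncrna_1", "pig", "ncRNA", 1000),
            ("pig_gdna_1", "pig", "genomic_DNA", 5000),
            ("pig_mito_1", "pig", "mitochondrial", 16000),
            ("nonvert_1", "non_vertebrate", "mRNA_cDNA", 1500),
            ("weak_1", "pig", "mRNA_cDNA", 800),
        ],
        columns=["subject_id", "species_class", "biotype", "length"],
    ).to_csv(subject_meta_tsv, sep="\t", index=False)

    # ---------------- CAGE TSS clusters -----------------------------------
    cage_tsv = outdir / "cage_clusters.tsv"
    crows = []
    for g in full_genes + truncated_genes:
        tss = g.tss
        crows.append((g.scaffold, max(0, tss - 20), tss + 21, g.strand, tss, "pig_macrophage"))
    crows.append((scaffold_ids[0], 97_000, 97_041, "+", 97_020, "pig_macrophage"))  # decoy
    pd.DataFrame(
        crows, columns=["scaffold", "start", "end", "strand", "dominant_tss", "source"]
    ).to_csv(cage_tsv, sep="\t", index=False)

    # ---------------- IsoSeq chains (GTF) ----------------------------------
    isoseq_gtf = outdir / "isoseq.gtf"
    iso_lines = []

    def iso_feature(tid, scaffold, strand, exons):
        for s, e in exons:
            attrs = f'gene_id "{tid}"; transcript_id "{tid}";'
            iso_lines.append(
                f"{scaffold}\tisoseq\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}"
            )

    for g in full_genes + truncated_genes:
        exons = list(g.exons)
        for r in range(2):
            ext = 30 + 10 * r  # termini differ from the assembled PT; introns match
            longer = [
                (exons[0][0] - ext, exons[0][1]),
                *exons[1:-1],
                (exons[-1][0], exons[-1][1] + ext),
            ]
            iso_feature(f"iso_{g.gene_id}_{r + 1}", g.scaffold, g.strand, longer)
    isoseq_gtf.write_text("\n".join(iso_lines) + "\n")

    # ---------------- reference annotation GTF -----------------------------
    reference_gtf = outdir / "reference.gtf"
    ref_lines = []
    for g in full_genes:
        # trimmed termini, identical introns: PTs extend both ends
        exons = list(g.exons)
        trimmed = [
            (exons[0][0] + 50, exons[0][1]),
            *exons[1:-1],
            (exons[-1][0], exons[-1][1] - 50),
        ]
        tid = f"ref_{g.gene_id}"
        for s, e in trimmed:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
            ref_lines.append(
                f"{g.scaffold}\tensembl\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}"
            )
    for g in truncated_genes:
        tid = f"ref_{g.gene_id}"
        for s, e in g.exons:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
            ref_lines.append(
                f"{g.scaffold}\tensembl\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}"
            )
    reference_gtf.write_text("\n".join(ref_lines) + "\n")

    # ---------------- genome + truth ---------------------------------------
    genome_fasta = outdir / "genome.fa"
    genome.to_fasta(genome_fasta)
    truth_tsv = outdir / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_tsv, sep="\t", index=False)

    return SyntheticDataset(
        genome_fasta=genome_fasta,
        pt_sam=pt_sam,
        gg_gtf=gg_gtf,
        reads_sam=reads_sam,
        junction_tsv=junction_tsv,
        blast_tsv=blast_tsv,
        subject_meta_tsv=subject_meta_tsv,
        cage_tsv=cage_tsv,
        isoseq_gtf=isoseq_gtf,
        reference_gtf=reference_gtf,
        truth_tsv=truth_tsv,
        genes=genes,
    )
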