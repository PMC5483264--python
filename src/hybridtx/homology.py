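"""Homology-based annotation from BLAST tabular output.

Top hits (ranked by bitscore, then E-value, then subject id) drive three
decisions: contaminant flagging (non-vertebrate top hit without a better
scoring genome alignment), mitochondrial exclusion, and biotype assignment.
Subject species class and biotype come from a metadata sidecar rather than
live taxonomy lookups. Full-length coverage of a subject by a query is
computed either from the single best HSP ("ungrouped") or from the union of
all HSP subject intervals ("grouped").
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

RNA_BIOTYPES = {"mRNA_cDNA", "ncRNA", "misc_RNA"}
BIOTYPES = RNA_BIOTYPES | {"genomic_DNA", "mitochondrial"}
SPECIES_CLASSES = {"pig", "other_vertebrate", "non_vertebrate"}


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    bitscore: float
    query_start: int  # 0-based half-open, strand-normalized
    query_end: int
    subject_start: int
    subject_end: int
    hsp_index: int = 0


@dataclass(frozen=True)
class SubjectMeta:
    subject_id: str
    species_class: str
    biotype: str
    subject_length: int

    def __post_init__(self) -> None:
        if self.species_class not in SPECIES_CLASSES:
            raise ValueError(f"{self.subject_id}: unknown species class {self.species_class!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.subject_id}: unknown biotype {self.biotype!r}")


@dataclass(frozen=True)
class TopHitAnnotation:
    pt_id: str
    is_significant: bool
    top_subject: str | None = None
    evalue: float | None = None
    bitscore: float | None = None
    species_class: str | None = None
    biotype: str | None = None


def read_blast_tsv(path) -> dict[str, list[BlastHit]]:
    """outfmt-6 table grouped by query; 1-based inclusive coordinates are
    converted and subject strand normalized (start <= end)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(OUTFMT6_COLUMNS)]
    df.columns = OUTFMT6_COLUMNS
    hits: dict[str, list[BlastHit]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        sstart, send = sorted((int(row.sstart), int(row.send)))
        qstart, qend = sorted((int(row.qstart), int(row.qend)))
        hits.setdefault(str(row.qseqid), []).append(
            BlastHit(
                query_id=str(row.qseqid),
                subject_id=str(row.sseqid),
                percent_identity=float(row.pident),
                evalue=float(row.evalue),
                bitscore=float(row.bitscore),
                query_start=qstart - 1,
                query_end=qend,
                subject_start=sstart - 1,
                subject_end=send,
                hsp_index=i,
            )
        )
    return hits


def read_subject_meta(path) -> dict[str, SubjectMeta]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        str(row.subject_id): SubjectMeta(
            str(row.subject_id), str(row.species_class), str(row.biotype), int(row.length)
        )
        for row in df.itertuples(index=False)
    }


def _rank_key(hit: BlastHit):
    return (-hit.bitscore, hit.evalue, hit.subject_id)


def select_top_hit(
    hits: list[BlastHit],
    meta: dict[str, SubjectMeta],
    evalue_cutoff: float = 1e-20,
) -> TopHitAnnotation:
    """Best significant hit under (bitscore desc, evalue asc, subject_id asc)."""
    if not hits:
        return TopHitAnnotation(pt_id="", is_significant=False)
    pt_id = hits[0].query_id
    significant = [h for h in hits if h.evalue <= evalue_cutoff]
    if not significant:
        return TopHitAnnotation(pt_id=pt_id, is_significant=False)
    best = min(significant, key=_rank_key)
    if best.subject_id not in meta:
        raise KeyError(f"no subject metadata for {best.subject_id}")
    m = meta[best.subject_id]
    return TopHitAnnotation(
        pt_id=pt_id,
        is_significant=True,
        top_subject=best.subject_id,
        evalue=best.evalue,
        bitscore=best.bitscore,
        species_class=m.species_class,
        biotype=m.biotype,
    )


def flag_contaminant(top: TopHitAnnotation, genome_best_score: float | None = None) -> bool:
    """Non-vertebrate top hit without a better-scoring genome alignment."""
    if not top.is_significant or top.species_class != "non_vertebrate":
        return False
    return genome_best_score is None or genome_best_score <= top.bitscore


def flag_mitochondrial(top: TopHitAnnotation) -> bool:
    return top.is_significant and top.biotype == "mitochondrial"


def full_length_coverage(
    hits_for_pair: list[BlastHit],
    subject_length: int,
    mode: str = "grouped",
) -> float:
    """Fraction of the subject covered by the query's HSPs.

    ungrouped: subject span of the single best HSP / subject length;
    grouped: |union of all HSP subject intervals| / subject length.
    """
    if subject_length <= 0:
        raise ValueError("subject_length must be positive")
    if not hits_for_pair:
        return 0.0
    if mode == "ungrouped":
        best = min(hits_for_pair, key=_rank_key)
        return (best.subject_end - best.subject_start) / subject_length
    if mode == "grouped":
        covered = 0
        last_end = None
        for start, end in sorted((h.subject_start, h.subject_end) for h in hits_for_pair):
            if last_end is None or start > last_end:
                covered += end - start
                last_end = end
            elif end > last_end:
                covered += end - last_end
                last_end = end
        return covered / subject_length
    raise ValueError(f"unknown coverage mode {mode!r}")


def reciprocal_best_hits(
    hits_ab: dict[str, list[BlastHit]],
    hits_ba: dict[str, list[BlastHit]],
    evalue_cutoff: float = 1e-20,
) -> list[tuple[str, str]]:
    """(a, b) pairs where b is a's best significant A->B hit and a is b's best
    significant B->A hit."""

    def best_map(table: dict[str, list[BlastHit]]) -> dict[str, str]:
        out = {}
        for qid, hits in table.items():
            significant = [h for h in hits if h.evalue <= evalue_cutoff]
            if significant:
                out[qid] = min(significant, key=_rank_key).subject_id
        return out

    fwd = best_map(hits_ab)
    rev = best_map(hits_ba)
    return sorted((a, b) for a, b in fwd.items() if rev.get(b) == a)
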