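"""GTF reading/writing for exon chains.

GTF is 1-based inclusive; everything in memory is 0-based half-open.
Reading requires gene_id/transcript_id attributes and uses exon features
only. Writing emits one transcript line plus its exon lines, with optional
extra attributes (mapping_category, splice_status, component tags ...).
"""

from __future__ import annotations

from collections import OrderedDict

from gffutils.iterators import DataIterator

from .model import NO_STRAND, ExonChain, TranscriptAlignment


def read_gtf_chains(path, source: str = "genome_guided") -> list[ExonChain]:
    """Exon chains from a GTF, one per transcript_id, in file order."""
    exons: "OrderedDict[str, dict]" = OrderedDict()
    for feat in DataIterator(str(path)):
        if feat.featuretype != "exon":
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise ValueError(f"GTF exon without transcript_id at {feat.seqid}:{feat.start}") from exc
        entry = exons.setdefault(
            tid, {"scaffold": feat.seqid, "strand": feat.strand or NO_STRAND, "exons": []}
        )
        if entry["scaffold"] != feat.seqid:
            raise ValueError(f"transcript {tid} has exons on multiple scaffolds")
        entry["exons"].append((feat.start - 1, feat.end))
    chains = []
    for tid, entry in exons.items():
        strand = entry["strand"] if entry["strand"] in "+-" else NO_STRAND
        chains.append(
            ExonChain(
                pt_id=tid,
                scaffold=entry["scaffold"],
                strand=strand,
                exons=tuple(sorted(entry["exons"])),
                source=source,
            )
        )
    return chains


def read_gtf_gene_ids(path) -> dict[str, str]:
    """transcript_id -> gene_id mapping from a GTF."""
    mapping: dict[str, str] = {}
    for feat in DataIterator(str(path)):
        attrs = feat.attributes
        if "transcript_id" in attrs and "gene_id" in attrs:
            mapping.setdefault(attrs["transcript_id"][0], attrs["gene_id"][0])
    return mapping


def _fmt_attrs(attrs: dict[str, str]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in attrs.items())


def write_gtf_chains(
    path,
    chains: list[ExonChain],
    gene_ids: dict[str, str] | None = None,
    extra_attrs: dict[str, dict[str, str]] | None = None,
    feature_source: str = "hybridtx",
) -> None:
    """Write chains as transcript + exon GTF features."""
    with open(path, "w") as fh:
        for chain in chains:
            gene = (gene_ids or {}).get(chain.pt_id, chain.pt_id)
            attrs = {"gene_id": gene, "transcript_id": chain.pt_id}
            attrs.update((extra_attrs or {}).get(chain.pt_id, {}))
            strand = chain.strand if chain.strand in "+-" else "."
            fh.write(
                "\t".join(
                    [
                        chain.scaffold,
                        feature_source,
                        "transcript",
                        str(chain.start + 1),
                        str(chain.end),
                        ".",
                        strand,
                        ".",
                        _fmt_attrs(attrs),
                    ]
                )
                + "\n"
            )
            for start, end in chain.exons:
                fh.write(
                    "\t".join(
                        [
                            chain.scaffold,
                            feature_source,
                            "exon",
                            str(start + 1),
                            str(end),
                            ".",
                            strand,
                            ".",
                            _fmt_attrs(attrs),
                        ]
                    )
                    + "\n"
                )


def write_gtf_alignments(path, alignments: list[TranscriptAlignment]) -> None:
    """Classified transcripts as GTF with mapping/splice/strand attributes.

    Translocation parts are written as separate features sharing the
    transcript_id, distinguished by a part attribute.
    """
    with open(path, "w") as fh:
        for aln in alignments:
            for idx, part in enumerate(aln.parts):
                attrs = {
                    "gene_id": aln.pt_id,
                    "transcript_id": aln.pt_id,
                    "mapping_category": aln.mapping_category,
                    "splice_status": aln.splice_status,
                    "strand_call": part.strand,
                }
                if len(aln.parts) > 1:
                    attrs["part"] = str(idx + 1)
                if aln.clipped:
                    attrs["clipped"] = "true"
                strand = part.strand if part.strand in "+-" else "."
                row = [
                    part.scaffold,
                    "hybridtx",
                    "transcript",
                    str(part.start + 1),
                    str(part.end),
                    ".",
                    strand,
                    ".",
                    _fmt_attrs(attrs),
                ]
                fh.write("\t".join(row) + "\n")
                for start, end in part.exons:
                    row[2] = "exon"
                    row[3] = str(start + 1)
                    row[4] = str(end)
                    fh.write("\t".join(row) + "\n")
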