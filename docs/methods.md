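# Methods

This note records the rules the package implements, the parameters that
matter, the choices made where the procedure was genuinely open, and what
the synthetic data does and does not establish.

## Coordinates and data model

All internal coordinates are 0-based half-open on the forward genome strand.
SAM (1-based) and GTF (1-based inclusive) are converted at the I/O boundary;
BED and bedGraph are native. A transcript is an ordered chain of
non-overlapping exon intervals; its introns are the gaps between consecutive
exons. Working in a single convention end to end avoids off-by-one drift in
junction comparisons, which are base-exact throughout.

## Mapping classification

A putative transcript (PT) is **unmapped** when all its SAM records carry
the unmapped flag; **multi-mapping** when any secondary alignment sits at a
locus distinct from the primary (identical-locus secondaries are collapsed
as duplicates); a **translocation** when its primary plus one supplementary
part lie on different scaffolds or more than `translocation_distance`
(default 2,000,000) bases apart on one scaffold; otherwise **unique**. More
than two non-secondary parts do not form a translocation and are classified
multi-mapping with a log warning. Exon blocks are the reference spans of
M/=/X/D CIGAR runs split only at N runs: a deletion stays inside its exon
because splicing is keyed to `N` alone. Soft/hard clips never move exon
boundaries; their presence is flagged per PT so downstream users can see
which termini are untrustworthy. PTs whose query is shorter than
`min_pt_length` (default 201 bases, i.e. products of ≤ 200 bases are
discarded) are dropped at ingest.

Splice status: unique/translocation PTs with at least one N-derived intron
in any part are spliced, without one unspliced; for multi-mapping and
unmapped PTs the status is undetermined and no strand or noise label is ever
assigned to them.

## Strand inference

De novo assemblers emit transcripts in arbitrary orientation, so the sense
strand is read off the genome. Forward-genome donor/acceptor dinucleotides
GT–AG, GC–AG, AT–AC imply '+'; their reverse complements CT–AC, CT–GC,
GT–AT imply '−'. Each intron votes and the majority wins. Ties (including
zero recognizable consensi, and all mono-exon chains) leave the strand
undetermined; such PTs are kept but excluded from every strand-dependent
comparison. Majority vote rather than unanimity was chosen deliberately:
single mis-assembled junctions should not discard an otherwise consistent
multi-intron transcript; unanimity would only shrink the strand-identifiable
subset.

## Intron catalog and noise labels

The catalog is the set union of (i) introns of spliced uniquely/translocation
mapping de novo PTs, (ii) introns of spliced genome-guided PTs, and (iii)
splice junctions supported by at least `min_junction_support` (default 3)
uniquely mapped spliced reads. Identical intervals merge their evidence
tags; junction intervals must match base-exactly to merge, since splice
sites are base-exact — near-miss junctions stay separate entries.

A mono-exon PT is **intronic** iff its span overlaps any cataloged intron by
at least one base, strand-agnostically; "with or without exonic sequence"
means any overlap counts and no minimum fraction is imposed. Intronic
mono-exon PTs are treated wholesale as transcriptional noise; the package
deliberately does not try to distinguish retained-intron isoforms or
pre-mRNA — that is outside its contract.

## Coverage and the low-coverage rule

Coverage per base (CPB) counts primary read alignments in split (N-aware)
mode: the intron gap of a spliced read contributes no depth. The
implementation accumulates interval deltas and prefix-sums them; tests pin
it to a naive per-base counter. No MAPQ floor is applied by default
(`min_mapq = 0`, configurable). An unspliced non-intronic PT is removed
when the **maximum** CPB over its own genomic span (leftmost to rightmost
mapped base) is strictly below `cpb_threshold` (default 50); a maximum of
exactly 50 is kept. The PT's own span is the only per-PT-computable reading
of "the genomic region" a PT occupies, and the maximum (not mean) is used so
that a single well-covered patch suffices to rescue a fragment.

## Homology annotation

BLAST tabular (outfmt 6) hits are ranked by bitscore (desc), then E-value
(asc), then subject id (asc) — the last key is an explicit determinism
tie-break, since "top hit" is otherwise ill-defined among equal scores.
Significance is E ≤ `evalue_nt` (1e-20) for nucleotide searches and
`evalue_nr` (1e-6) for protein searches. Subject species class
(pig / other vertebrate / non-vertebrate) and biotype (mRNA/cDNA, ncRNA,
misc_RNA, genomic DNA, mitochondrial) come from a metadata sidecar table
rather than live taxonomy lookups, keeping the pipeline fully offline.

A PT is a **contaminant** when its top hit is non-vertebrate and it has no
better-scoring genome alignment; the score comparison is a direct ≤ on the
supplied scores, because BLAST bitscores and aligner scores live on
different scales there is no principled universal conversion — callers can
rescale before passing `genome_scores`. **Mitochondrial** means the top-hit
biotype is mitochondrial. Full-length coverage of a subject by a query is
either the best HSP's subject span over the subject length ("ungrouped") or
the union of all HSP subject intervals over the subject length ("grouped");
grouped ≥ ungrouped always. Reciprocal best hits require mutual top rank
with both directions significant.

## Filter cascade

Stages run in a fixed order — mitochondrial, unspliced intronic,
contaminant, low-coverage non-intronic, unanchored multi/unmapped — and a PT
is counted at the first stage that removes it, which makes the per-stage
counts reproducible and summable: `output_n = input_n − Σ removed`. Stage 5
keeps multi/unmapped PTs whose top-hit biotype is mRNA/cDNA, ncRNA or
misc_RNA. The same code path runs on both assemblies; the genome-guided
assembly simply has no contaminant flags and no multi/unmapped PTs, so those
stages remove nothing from it. An unspliced mapped PT reaching the cascade
without an intronic/non-intronic label is a pipeline-ordering bug and raises
immediately rather than passing silently.

## Integration and gene loci

Two PTs **share** a feature when an intron of one is coordinate-identical to
an intron of the other, or an exon is coordinate-identical (both
boundaries). Exact exon equality was chosen for symmetry with introns and
determinism; overlap-based exon sharing is available as
`exon_share = overlap` for sensitivity analysis. The integrated set is:

- **A** — all filtered de novo spliced PTs (unique and translocation);
- **B** — filtered genome-guided spliced PTs with no same-strand shared
  intron/exon with any stranded member of A; strand-undetermined de novo PTs
  do not block B, and strand-undetermined genome-guided spliced PTs are
  excluded from B with a warning because the same-strand rule cannot apply;
- **C** — filtered de novo unspliced non-intronic PTs;
- **D** — filtered genome-guided unspliced non-intronic PTs with no ≥ 1-base
  strand-agnostic overlap with any C member (strands of unspliced PTs are
  unknowable here, hence strand-agnostic);
- **E** — multi/unmapped de novo PTs that survived stage 5.

Components are disjoint by construction and their sizes always sum to the
total. Integration is idempotent (integrating an assembly with itself gives
B = D = ∅) and independent of input order.

A **gene locus** is a connected component of the sharing relation among
stranded spliced PTs per (scaffold, strand) — transitive closure, so two PTs
that share nothing directly still join one locus through an intermediary.

## Validation

IsoSeq support: **full** when the PT's ordered intron chain equals that of
at least one same-strand IsoSeq chain (terminal exon boundaries free —
long reads legitimately extend termini); **partial** when any intron or exon
is shared; otherwise **none**. Full implies the partial criterion, and the
three statuses partition the compared set.

CAGE: a proximal promoter is the dominant TSS of a cluster ± `promoter_flank`
(default 50) bases, a 101-base interval clipped at scaffold bounds (a
one-sided reading of the flank is selectable in principle but the symmetric
one is the default and the one tested). A PT is 5′-complete when a
same-strand promoter overlaps its first exon, restricted to the 5′-most
`first_exon_window` (default 500) bases when the exon is longer. Promoter
distance is reported separately with closest-feature semantics
(strand-matched; gap of 0 inside a promoter; sign positive when the promoter
is upstream of the 5′ terminus); completeness and distance are computed as
two independent read-outs, not combined.

## Reference comparison

Against a reference transcript set (restricted to spliced, uniquely mapping,
stranded references before comparison), each PT is **identical_junctions**
(equal intron chain, same strand), else **shared_gene** (≥ 1 shared intron
or exon), else **novel**. The anchor for terminus comparison is the
reference with maximal exonic-base overlap (not span overlap, which would
reward long introns), ties broken by shared-intron count then id. "Longer"
terminus means strict genomic extension — equality is not longer — and
5′/3′ are mirrored on the '−' strand. The residual class `mixed_or_equal`
holds equal and discordant layouts the four named classes miss. Gene
identifiers transfer to a PT from every reference it directly shares a
feature with; one PT can inherit several gene ids.

## Synthetic data

The generator plants, on a 3 × 100 kb random genome, 12 three-exon gene
models with consensus splice sites, and one PT (or more) per truth class:
clean spliced (6 full-length with CAGE clusters at their TSS and matching
IsoSeq chains, 2 truncated at the 5′ end), 2 novel-vs-reference, 2
genome-guided-only genes, 6 + 2 intronic fragments, 4 low-coverage and 3
keepable unspliced fragments (islands tiled at depth 49 and 55 — one read
below and five above the 50× rule), 3 contaminants, 2 mitochondrial-hit PTs,
2 translocations, 2 multi-mappers with RNA hits, 2 unanchored PTs, 4
genome-guided duplicates and 2 + 2 genome-guided unspliced keepers/
duplicates. Counts are realized exactly by construction, not sampled, and
identical (seed, config) yields byte-identical files. The default fixture is
small (~46 PTs) so the full test suite runs in seconds.

What the generator does **not** emulate: sequencing errors, expression-level
variation, polymorphism, fragmented or chimeric assembly artifacts beyond
the planted classes, and soft-clipped alignments. Passing tests therefore
establish that every filtering and comparison *rule* is implemented exactly
as specified on unambiguous inputs; they do not establish recovery rates on
real, noisy assemblies, where mapping ambiguity and imperfect junctions
blur the planted distinctions.

## Numerical and degenerate-input choices

- All thresholds are strict/inclusive exactly as stated above (≥ 3 junction
  reads supports an intron; CPB < 50 removes; E ≤ cutoff is significant).
- Empty inputs produce empty outputs and all-zero reports, never errors;
  malformed records (bad CIGAR, missing subject metadata, off-scaffold
  coordinates) raise errors naming the offending record.
- The only randomness in the package is the synthetic generator's seed; the
  pipeline proper is fully deterministic, and reports are byte-identical
  across reruns.

## Known limitations

- Exact-boundary exon sharing under-merges assemblies whose exon termini
  jitter by a few bases; the `overlap` mode trades that for over-merging.
- The contaminant "better genome alignment" clause compares scores on
  whatever scale the caller supplies; cross-program score comparison is
  inherently heuristic.
- 3′-completeness is not validated (no 3′-anchored evidence type is
  consumed).
- The CPB rule evaluates each PT's own span; a regional definition
  (e.g. merged transcribed blocks) would need a separate segmentation step
  and is not implemented.
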