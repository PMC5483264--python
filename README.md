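# hybridtx

Quality control and integration for hybrid transcriptome assemblies.

Short-read transcriptome assemblies — whether assembled de novo (Trinity-style)
or genome-guided (Cufflinks/StringTie-style) — are contaminated by
transcriptional noise: unspliced fragments of introns from incompletely
processed RNA, fragments assembled from thinly covered genomic regions,
sequences of non-vertebrate origin (microbes, feed), mitochondrial
transcripts, and chimeric or ambiguous mappings. `hybridtx` implements the
post-assembly bookkeeping that turns two raw assemblies of putative
transcripts (PTs) into one quality-filtered, integrated transcriptome, for
genomes whose annotation is too sparse to filter against directly. It is
aimed at groups building transcriptome resources for emerging model
organisms from heterogeneous public RNA-seq data.

## What it computes

Each de novo PT is aligned to the genome by a spliced aligner beforehand;
`hybridtx` consumes the SAM and classifies every PT by **mapping category**
(unique / multi-mapping / translocation / unmapped, where a translocation is
two alignment parts on different scaffolds or > 2 Mb apart) and **splice
status** (spliced iff an `N` CIGAR operation opens an intron; undetermined
for multi-mapping and unmapped PTs). The **sense strand** of each spliced PT
is recovered from the splice-site consensus dinucleotides (GT–AG, GC–AG,
AT–AC and their reverse complements) by a per-intron majority vote.

An **intron catalog** is built from three evidence sources: introns of
spliced de novo PTs, introns of spliced genome-guided PTs, and splice
junctions supported by ≥ 3 uniquely mapped spliced reads. Both assemblies
then pass an ordered five-stage filter cascade, with each removed PT
attributed to the first stage that catches it:

1. PTs whose top nucleotide-database hit (megaBLAST, E ≤ 1e-20) is
   mitochondrial;
2. unspliced PTs overlapping any cataloged intron by ≥ 1 base
   ("unspliced intronic" noise);
3. PTs whose top hit is non-vertebrate, unless they align better to the
   genome than to that hit (contaminants);
4. unspliced non-intronic PTs whose maximal coverage per base (CPB) over
   their span is below 50×;
5. multi-mapping/unmapped PTs without an RNA-biotype top hit.

The filtered assemblies are merged into five disjoint components:
**(A)** all de novo spliced PTs; **(B)** genome-guided spliced PTs sharing no
same-strand intron or exon with A; **(C)** de novo unspliced non-intronic
PTs; **(D)** genome-guided unspliced non-intronic PTs not overlapping C; and
**(E)** multi/unmapped de novo PTs with RNA top hits. Same-strand PTs that
share at least one intron or exon are clustered into gene loci (connected
components of the sharing relation).

The integrated set is then validated against IsoSeq full-length reads
(identical ordered intron chain = full support; any shared intron/exon =
partial) and against CAGE-derived proximal promoters (± 50 bases around each
dominant TSS; a PT is 5′-complete when a same-strand promoter overlaps the
5′-most 500 bases of its first exon), and compared with a reference
annotation (identical junctions / shared gene / novel; strand-aware terminus
extension against the maximally overlapping reference; gene-ID transfer).

A deterministic synthetic-data module generates every input with planted
truth labels, so the whole pipeline is testable offline.

## Worked example

```bash
hybridtx simulate --seed 1 --outdir fixture
hybridtx run --inputs fixture/inputs.yaml --outdir out
```

prints

```
wrote synthetic inputs and fixture/inputs.yaml
integrated_total=21; report in out
```

and `out/report.json` contains (excerpt):

```json
"components": {"A": 12, "B": 2, "C": 3, "D": 2, "E": 2},
"filter_denovo": {"input_n": 34, "removed_mito": 2,
                  "removed_unspliced_intronic": 6, "removed_contaminant": 3,
                  "removed_lowcov_nonintronic": 4, "removed_unanchored": 2,
                  "output_n": 17},
"intron_catalog_n": 27,
"isoseq_status": {"full": 6, "none": 4, "partial": 2},
"cage_complete_n": 6,
"ref_relation": {"identical_junctions": 6, "novel": 4, "shared_gene": 2}
```

Reading: of 34 de novo PTs, 17 survive the cascade (2 mitochondrial, 6
unspliced intronic, 3 contaminants, 4 low-coverage fragments and 2
unanchored PTs removed — exactly the planted noise); the integrated
transcriptome holds 21 PTs across the five components; all 6 planted
full-length genes are fully IsoSeq-supported and CAGE-5′-complete; the 4
PTs at genes absent from the reference annotation are called novel. Every
count equals the generator's truth table.

The same stages are callable as a library (`hybridtx.run_pipeline`,
`hybridtx.apply_filter_cascade`, `hybridtx.integrate`, ...) or individually
as `hybridtx classify|filter|integrate|validate|compare|report` over one
state directory.

## Layout

- `src/hybridtx/model.py` — exon chains, sharing/identity relations
- `src/hybridtx/alignments.py`, `strand.py`, `genome.py`, `gtfio.py` — I/O
  and classification
- `src/hybridtx/noise.py` — intron catalog, CPB, low-coverage rule
- `src/hybridtx/homology.py` — BLAST top hits, contaminant/mito flags, HSP
  coverage, reciprocal best hits
- `src/hybridtx/integrator.py` — filter cascade, five-component merge, gene
  loci
- `src/hybridtx/validator.py`, `ref_compare.py` — IsoSeq/CAGE validation,
  reference comparison
- `src/hybridtx/simulate.py` — synthetic data with truth tables
- `src/hybridtx/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — models, rules, parameters and design decisions
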