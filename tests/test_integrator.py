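"""Filter cascade ordering, assembly integration and gene-locus clustering."""

import numpy as np
import pytest

from hybridtx import (
    ExonChain,
    TranscriptAlignment,
    apply_filter_cascade,
    cluster_genes,
    integrate,
)
from hybridtx.homology import TopHitAnnotation
from hybridtx.integrator import (
    STAGE_CONTAMINANT,
    STAGE_INTRONIC,
    STAGE_LOWCOV,
    STAGE_MITO,
    STAGE_UNANCHORED,
)
from hybridtx.model import MULTI, SPLICED, UNIQUE, UNMAPPED, UNSPLICED
from hybridtx.noise import INTRONIC, NON_INTRONIC, CoverageTrack


def aln(pt_id, exons=((0, 300),), category=UNIQUE, scaffold="s1", strand="+",
        source="denovo"):
    parts = []
    if exons is not None:
        parts = [ExonChain(pt_id, scaffold, strand, tuple(exons), source)]
    status = "undetermined"
    if category in (UNIQUE, "translocation") and parts:
        status = SPLICED if len(exons) > 1 else UNSPLICED
    return TranscriptAlignment(pt_id=pt_id, parts=parts, mapping_category=category,
                               splice_status=status, source=source)


def top(pt_id, species="pig", biotype="mRNA_cDNA", bitscore=400.0, significant=True):
    if not significant:
        return TopHitAnnotation(pt_id, False)
    return TopHitAnnotation(pt_id, True, "subj", 1e-40, bitscore, species, biotype)


def flat_track(depth, length=10_000):
    return CoverageTrack({"s1": np.full(length, depth, dtype=np.int64)})


class TestFilterCascade:
    def test_stagewise_attribution_and_conservation(self):
        """Planted one-per-class removals are attributed to the right stage
        and the report sums exactly."""
        pts = (
            [aln(f"clean{i}", ((0, 100), (500, 600))) for i in range(5)]
            + [aln("mito1"), aln("mito2")]
            + [aln(f"intr{i}") for i in range(3)]
            + [aln("contam1", ((0, 100), (500, 600)))]
            + [aln(f"low{i}") for i in range(2)]
            + [aln("un1", None, category=UNMAPPED), aln("un2", exons=((0, 200),), category=MULTI)]
        )
        tophits = {p.pt_id: top(p.pt_id) for p in pts}
        tophits["mito1"] = top("mito1", biotype="mitochondrial")
        tophits["mito2"] = top("mito2", biotype="mitochondrial")
        tophits["contam1"] = top("contam1", species="non_vertebrate")
        tophits["un1"] = top("un1", significant=False)
        tophits["un2"] = top("un2", biotype="genomic_DNA")
        labels = {p.pt_id: NON_INTRONIC for p in pts if p.unspliced}
        for i in range(3):
            labels[f"intr{i}"] = INTRONIC
        track = flat_track(0)  # nothing reaches 50x: every non-intronic drops

        kept, report = apply_filter_cascade(pts, tophits, labels, track)
        assert report.as_dict() == {
            "input_n": 15, "removed_mito": 2, "removed_unspliced_intronic": 3,
            "removed_contaminant": 1, "removed_lowcov_nonintronic": 2,
            "removed_unanchored": 2, "output_n": 5,
        }
        assert {a.pt_id for a in kept} == {f"clean{i}" for i in range(5)}
        assert report.removed["mito1"] == STAGE_MITO
        assert report.removed["intr0"] == STAGE_INTRONIC
        assert report.removed["contam1"] == STAGE_CONTAMINANT
        assert report.removed["low0"] == STAGE_LOWCOV
        assert report.removed["un1"] == STAGE_UNANCHORED

    def test_first_stage_wins_for_doubly_removable_pt(self):
        """Mitochondrial AND intronic is counted at the mitochondrial stage."""
        pts = [aln("both")]
        tophits = {"both": top("both", biotype="mitochondrial")}
        _, report = apply_filter_cascade(pts, tophits, {"both": INTRONIC}, flat_track(100))
        assert report.removed["both"] == STAGE_MITO
        assert report.removed_unspliced_intronic == 0

    def test_empty_input(self):
        kept, report = apply_filter_cascade([], {}, {}, flat_track(0))
        assert kept == [] and report.as_dict()["input_n"] == 0
        assert report.total_removed() == 0

    def test_unlabeled_unspliced_pt_is_a_pipeline_order_error(self):
        with pytest.raises(RuntimeError, match="noise classification"):
            apply_filter_cascade([aln("u1")], {}, {}, flat_track(100))

    def test_multi_with_rna_hit_survives_stage_five(self):
        pts = [aln("m1", exons=((0, 200),), category=MULTI)]
        kept, _ = apply_filter_cascade(pts, {"m1": top("m1", biotype="ncRNA")}, {}, flat_track(0))
        assert [a.pt_id for a in kept] == ["m1"]

    def test_cpb_threshold_zero_removes_nothing_at_stage_four(self):
        pts = [aln(f"p{i}") for i in range(5)]
        labels = {p.pt_id: NON_INTRONIC for p in pts}
        _, report = apply_filter_cascade(pts, {}, labels, flat_track(0), cpb_threshold=0)
        assert report.removed_lowcov_nonintronic == 0


def spliced(pt_id, exons, strand="+", scaffold="s1", source="denovo", category=UNIQUE):
    return aln(pt_id, exons, category=category, scaffold=scaffold, strand=strand,
               source=source)


class TestIntegrate:
    a_exons = ((0, 100), (500, 700))

    def test_gg_sharing_intron_excluded_from_b(self):
        dn = [spliced("dn1", self.a_exons)]
        gg = [spliced("gg1", ((50, 100), (500, 800)), source="genome_guided")]
        result = integrate(dn, gg)
        assert result.component_sizes() == {"A": 1, "B": 0, "C": 0, "D": 0, "E": 0}

    def test_opposite_strand_identical_coordinates_retained_in_b(self):
        dn = [spliced("dn1", self.a_exons, strand="+")]
        gg = [spliced("gg1", self.a_exons, strand="-", source="genome_guided")]
        result = integrate(dn, gg)
        assert result.component_sizes()["B"] == 1

    def test_unstranded_gg_spliced_pt_cannot_enter_b(self):
        dn = [spliced("dn1", self.a_exons)]
        gg = [spliced("gg1", ((2000, 2100), (2500, 2600)), strand=".",
                      source="genome_guided")]
        result = integrate(dn, gg)
        assert result.component_sizes()["B"] == 0

    def test_unspliced_overlap_with_c_is_strand_agnostic(self):
        dn = [spliced("dn1", ((1000, 1300),), strand="+")]
        gg = [
            spliced("gg1", ((1200, 1500),), strand="-", source="genome_guided"),
            spliced("gg2", ((5000, 5300),), strand="-", source="genome_guided"),
        ]
        result = integrate(dn, gg)
        assert result.component_sizes()["C"] == 1
        assert [a.pt_id for a in result.components["D"]] == ["gg2"]

    def test_self_integration_is_idempotent(self):
        dn = [
            spliced("p1", self.a_exons),
            spliced("p2", ((1000, 1300),)),
            spliced("p3", ((2000, 2100), (2500, 2700)), strand="-"),
        ]
        result = integrate(dn, dn)
        assert result.component_sizes()["B"] == 0
        assert result.component_sizes()["D"] == 0

    def test_conservation_and_order_independence(self):
        rng = np.random.default_rng(17)
        dn, gg = [], []
        for i in range(40):
            pos = int(rng.integers(0, 50_000))
            exons = ((pos, pos + 100), (pos + 400, pos + 600))
            dn.append(spliced(f"dn{i}", exons, strand="+-"[i % 2]))
            if i % 3 == 0:  # share introns with dn
                gg.append(spliced(f"gg{i}", exons, strand="+-"[i % 2],
                                  source="genome_guided"))
            else:
                gg.append(spliced(f"gg{i}", ((pos + 10_000, pos + 10_200),
                                             (pos + 10_500, pos + 10_650)),
                                  strand="+-"[i % 2], source="genome_guided"))
        base = integrate(dn, gg)
        assert base.total == sum(base.component_sizes().values())
        perm = integrate(list(reversed(dn)), list(reversed(gg)))
        for comp in "ABCDE":
            assert {a.pt_id for a in base.components[comp]} == {
                a.pt_id for a in perm.components[comp]
            }


class TestClusterGenes:
    def c(self, pt_id, exons, strand="+"):
        return ExonChain(pt_id, "s1", strand, tuple(exons))

    def test_transitive_closure(self):
        a = self.c("A", [(0, 100), (500, 700)])
        b = self.c("B", [(0, 100), (500, 650), (900, 1000)])  # shares intron with A
        c = self.c("C", [(900, 1000), (1200, 1300)])  # shares exon with B only
        loci = cluster_genes([a, b, c])
        assert len(loci) == 1
        assert loci[0].pt_ids == ["A", "B", "C"]
        assert (loci[0].start, loci[0].end) == (0, 1300)

    def test_disjoint_pts_make_separate_loci(self):
        loci = cluster_genes([
            self.c("A", [(0, 100), (500, 700)]),
            self.c("B", [(2000, 2100), (2500, 2700)]),
        ])
        assert len(loci) == 2

    def test_strands_never_merge(self):
        loci = cluster_genes([
            self.c("A", [(0, 100), (500, 700)], strand="+"),
            self.c("B", [(0, 100), (500, 700)], strand="-"),
        ])
        assert len(loci) == 2

    def test_matches_union_find_oracle_and_partitions(self):
        """Components equal a hand-rolled union-find over the pairwise
        sharing relation, and every chain lands in exactly one locus."""
        from hybridtx.model import shares_intron_or_exon

        rng = np.random.default_rng(23)
        chains = []
        for i in range(120):
            pos = int(rng.integers(0, 3_000)) * 10
            n_ex = int(rng.integers(2, 4))
            exons, p = [], pos
            for _ in range(n_ex):
                e = p + int(rng.integers(1, 5)) * 10
                exons.append((p, e))
                p = e + int(rng.integers(1, 5)) * 10
            chains.append(self.c(f"pt{i}", exons, strand="+-"[int(rng.integers(2))]))

        parent = {c.pt_id: c.pt_id for c in chains}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for x in chains:
            for y in chains:
                if x.pt_id < y.pt_id and x.strand == y.strand and shares_intron_or_exon(x, y):
                    parent[find(x.pt_id)] = find(y.pt_id)
        oracle = {}
        for c_ in chains:
            oracle.setdefault(find(c_.pt_id), set()).add(c_.pt_id)

        loci = cluster_genes(chains)
        assert {frozenset(l.pt_ids) for l in loci} == {
            frozenset(v) for v in oracle.values()
        }
        assigned = [pt for l in loci for pt in l.pt_ids]
        assert sorted(assigned) == sorted(c_.pt_id for c_ in chains)
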