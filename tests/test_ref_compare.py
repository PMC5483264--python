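"""Reference comparison: relation labels, maximal overlap, terminus classes,
gene-ID transfer."""

import numpy as np
import pytest

from hybridtx import (
    ExonChain,
    classify_termini,
    compare_to_reference,
    maximal_overlap_ref,
)
from hybridtx.ref_compare import (
    BOTH_LONGER,
    BOTH_SHORTER,
    IDENTICAL_JUNCTIONS,
    LONGER_3_ONLY,
    LONGER_5_ONLY,
    MIXED_OR_EQUAL,
    NOVEL,
    SHARED_GENE,
    exonic_overlap,
    transfer_gene_ids,
)


def chain(exons, pt_id="pt1", strand="+", scaffold="s1", source="denovo"):
    return ExonChain(pt_id, scaffold, strand, tuple(exons), source)


REFS = [
    chain([(100, 200), (500, 700)], pt_id="ref1", source="reference"),
    chain([(2000, 2200), (2600, 2800)], pt_id="ref2", source="reference"),
]


class TestRelations:
    def test_identical_junctions(self):
        pt = chain([(50, 200), (500, 800)])  # same intron, longer termini
        records = compare_to_reference([pt], REFS)
        assert records["pt1"].relation == IDENTICAL_JUNCTIONS
        assert records["pt1"].best_ref_id == "ref1"

    def test_shared_exon_only(self):
        pt = chain([(100, 200), (900, 1000)])
        records = compare_to_reference([pt], REFS)
        assert records["pt1"].relation == SHARED_GENE

    def test_novel(self):
        pt = chain([(9000, 9100), (9500, 9600)])
        records = compare_to_reference([pt], REFS)
        assert records["pt1"].relation == NOVEL
        assert records["pt1"].best_ref_id is None
        assert records["pt1"].terminus_class == "NA"
        assert records["pt1"].transferred_gene_ids == []

    def test_relations_partition_the_input(self):
        pts = [
            chain([(50, 200), (500, 800)], pt_id="a"),
            chain([(100, 200), (900, 1000)], pt_id="b"),
            chain([(9000, 9100), (9500, 9600)], pt_id="c"),
        ]
        records = compare_to_reference(pts, REFS)
        assert sorted(r.relation for r in records.values()) == sorted(
            [IDENTICAL_JUNCTIONS, SHARED_GENE, NOVEL]
        )

    def test_reference_vs_itself_all_identical_and_equal_termini(self):
        records = compare_to_reference(REFS, REFS)
        assert all(r.relation == IDENTICAL_JUNCTIONS for r in records.values())
        assert all(r.terminus_class == MIXED_OR_EQUAL for r in records.values())
        assert all(r.best_ref_id == pt_id for pt_id, r in records.items())


class TestMaximalOverlap:
    def test_largest_exonic_overlap_wins(self):
        pt = chain([(100, 1000)])
        refs = [
            chain([(100, 500)], pt_id="small", source="reference"),
            chain([(100, 1000)], pt_id="big", source="reference"),
        ]
        assert maximal_overlap_ref(pt, refs) == "big"

    def test_tie_broken_by_shared_introns_then_id(self):
        pt = chain([(0, 500), (800, 1300)])
        refs = [
            chain([(0, 500), (800, 1300)], pt_id="zz_shares", source="reference"),
            chain([(0, 600), (750, 1300)], pt_id="aa_span", source="reference"),
        ]
        # both overlap 1000 exonic bases; the intron-sharing ref wins despite id order
        assert exonic_overlap(pt, refs[0]) == exonic_overlap(pt, refs[1])
        assert maximal_overlap_ref(pt, refs) == "zz_shares"

    def test_matches_pairwise_overlap_sum_oracle(self):
        rng = np.random.default_rng(41)
        refs = []
        for i in range(80):
            pos = int(rng.integers(0, 50_000))
            refs.append(chain([(pos, pos + 300), (pos + 600, pos + 900)],
                              pt_id=f"r{i:03d}", source="reference"))
        for i in range(80):
            pos = int(rng.integers(0, 50_000))
            pt = chain([(pos, pos + 400), (pos + 700, pos + 1000)], pt_id=f"q{i}")
            got = maximal_overlap_ref(pt, refs)
            overlaps = {r.pt_id: exonic_overlap(pt, r) for r in refs}
            best = max(overlaps.values(), default=0)
            if best == 0:
                assert got is None
            else:
                assert overlaps[got] == best


class TestTermini:
    def test_plus_strand_both_longer(self):
        pt = chain([(100, 2000)])
        ref = chain([(200, 1800)], pt_id="r", source="reference")
        assert classify_termini(pt, ref) == BOTH_LONGER

    def test_minus_strand_mirror(self):
        pt = chain([(200, 1800)], strand="-")
        ref = chain([(200, 2000)], pt_id="r", strand="-", source="reference")
        # on '-', the 3' end is the genomic left end; pt extends neither left
        # nor right beyond the ref except... pt.end < ref.end -> 5' shorter
        assert classify_termini(pt, ref) == MIXED_OR_EQUAL

    def test_minus_strand_longer_3_only(self):
        pt = chain([(100, 1800)], strand="-")
        ref = chain([(200, 1800)], pt_id="r", strand="-", source="reference")
        assert classify_termini(pt, ref) == LONGER_3_ONLY

    def test_equal_termini(self):
        pt = chain([(100, 2000)])
        ref = chain([(100, 2000)], pt_id="r", source="reference")
        assert classify_termini(pt, ref) == MIXED_OR_EQUAL

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_antisymmetry_under_swap(self, strand):
        """both_longer and both_shorter swap under exchanging pt and ref;
        equal termini are a fixed point; one-sided classes never map to
        themselves."""
        rng = np.random.default_rng(43)
        for _ in range(100):
            a_start, b_start = rng.integers(0, 50, size=2)
            a_end, b_end = rng.integers(100, 150, size=2)
            a = chain([(int(a_start), int(a_end))], strand=strand)
            b = chain([(int(b_start), int(b_end))], pt_id="b", strand=strand)
            fwd, rev = classify_termini(a, b), classify_termini(b, a)
            if fwd == BOTH_LONGER:
                assert rev == BOTH_SHORTER
            elif fwd == BOTH_SHORTER:
                assert rev == BOTH_LONGER
            elif (a_start, a_end) == (b_start, b_end):
                assert fwd == rev == MIXED_OR_EQUAL
            elif fwd in (LONGER_3_ONLY, LONGER_5_ONLY):
                assert rev != fwd


class TestGeneIdTransfer:
    def test_single_and_bridging_transfer(self):
        refs = [
            chain([(100, 200), (500, 700)], pt_id="t1", source="reference"),
            chain([(500, 700), (900, 1000)], pt_id="t2", source="reference"),
        ]
        gene_ids = {"t1": "G1", "t2": "G2"}
        pts = [
            chain([(100, 200), (500, 650)], pt_id="only_g1"),
            chain([(100, 200), (500, 700), (900, 1000)], pt_id="bridge"),
            chain([(5000, 5100), (5500, 5600)], pt_id="novel"),
        ]
        mapping = transfer_gene_ids(pts, refs, gene_ids)
        assert mapping["only_g1"] == ["G1"]
        assert mapping["bridge"] == ["G1", "G2"]
        assert mapping["novel"] == []
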