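"""Intron catalog, intronic classification, per-base coverage and the
low-coverage filter."""

import numpy as np
import pytest

from hybridtx import (
    ExonChain,
    build_intron_catalog,
    classify_unspliced,
    compute_cpb,
    low_coverage_filter,
)
from hybridtx.noise import (
    DENOVO_SPLICED,
    DROP,
    GG_SPLICED,
    INTRONIC,
    JUNCTION_READS,
    KEEP,
    NON_INTRONIC,
    CoverageTrack,
    read_junction_tsv,
)

from conftest import make_sam


def chain(exons, pt_id="pt", strand="+", scaffold="s1", source="denovo"):
    return ExonChain(pt_id, scaffold, strand, tuple(exons), source)


class TestIntronCatalog:
    def test_evidence_merging_and_support_cutoff(self):
        dn = [chain([(0, 100), (500, 600)])]
        gg = [chain([(50, 100), (500, 650)], source="genome_guided")]
        catalog = build_intron_catalog(
            dn, gg, junctions=[(("s1", 800, 1200), 2)], min_support=3
        )
        assert set(catalog.evidence) == {("s1", 100, 500)}
        assert catalog.evidence[("s1", 100, 500)] == {DENOVO_SPLICED, GG_SPLICED}

    def test_support_boundary_at_least_three(self):
        catalog = build_intron_catalog([], [], [(("s1", 10, 50), 3)])
        assert ("s1", 10, 50) in catalog
        assert catalog.evidence[("s1", 10, 50)] == {JUNCTION_READS}

    def test_negative_support_rejected(self):
        with pytest.raises(ValueError):
            build_intron_catalog([], [], [(("s1", 10, 50), -1)])

    def test_union_matches_brute_force_oracle(self):
        """Catalog over random planted introns equals the exhaustive set union."""
        rng = np.random.default_rng(7)
        def random_spliced(n, source):
            chains = []
            for i in range(n):
                pos = int(rng.integers(0, 50_000))
                exons, p = [], pos
                for _ in range(int(rng.integers(2, 5))):
                    e = p + int(rng.integers(50, 300))
                    exons.append((p, e))
                    p = e + int(rng.integers(30, 500))
                chains.append(chain(exons, pt_id=f"{source}{i}", source=source))
            return chains

        dn = random_spliced(100, "dn")
        gg = random_spliced(100, "gg")
        junctions = [
            (("s1", int(s), int(s) + int(rng.integers(40, 400))), int(rng.integers(0, 6)))
            for s in rng.integers(0, 50_000, size=50)
        ]
        catalog = build_intron_catalog(dn, gg, junctions, min_support=3)
        oracle = set()
        for c in dn + gg:
            oracle |= {("s1", s, e) for s, e in c.introns}
        oracle |= {iv for iv, support in junctions if support >= 3}
        assert set(catalog.evidence) == oracle

    def test_min_support_monotonicity(self):
        rng = np.random.default_rng(11)
        junctions = [
            (("s1", int(s), int(s) + 100), int(rng.integers(0, 10)))
            for s in rng.integers(0, 10_000, size=60)
        ]
        sizes = [
            len(build_intron_catalog([], [], junctions, min_support=k))
            for k in range(0, 8)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestClassifyUnspliced:
    catalog = build_intron_catalog([chain([(0, 100), (500, 600)])], [], [])

    @pytest.mark.parametrize(
        "span, label",
        [
            ((150, 300), INTRONIC),  # contained in the intron
            ((90, 120), INTRONIC),  # partial overlap still counts
            ((600, 900), NON_INTRONIC),
            ((499, 500), INTRONIC),  # single shared base
            ((500, 501), NON_INTRONIC),  # abuts the intron end, no overlap
        ],
    )
    def test_single_base_overlap_rule(self, span, label):
        assert classify_unspliced(chain([span]), self.catalog) == label

    def test_spliced_input_rejected(self):
        with pytest.raises(ValueError):
            classify_unspliced(chain([(0, 10), (50, 60)]), self.catalog)

    def test_matches_all_pairs_overlap_oracle(self):
        rng = np.random.default_rng(3)
        introns = [
            ("s1", int(s), int(s) + int(rng.integers(50, 400)))
            for s in rng.integers(0, 100_000, size=300)
        ]
        catalog = build_intron_catalog(
            [], [], [(iv, 5) for iv in introns], min_support=3
        )
        trees = catalog.trees()
        for i, start in enumerate(rng.integers(0, 100_000, size=500)):
            span = (int(start), int(start) + int(rng.integers(50, 600)))
            pt = chain([span], pt_id=f"u{i}")
            expected = (
                INTRONIC
                if any(span[0] < e and span[1] > s for _, s, e in introns)
                else NON_INTRONIC
            )
            assert classify_unspliced(pt, catalog, trees) == expected


class TestCoverage:
    lengths = {"s1": 2_000, "s2": 2_000}

    def test_stacked_unspliced_reads(self, tmp_path):
        sam = make_sam(
            tmp_path / "r.sam",
            [(f"r{i}", 0, "s1", 0, "100M") for i in range(3)],
            scaffolds=self.lengths,
        )
        track = compute_cpb(sam, self.lengths)
        assert track.depth["s1"][:100].tolist() == [3] * 100
        assert track.depth["s1"][100:].sum() == 0

    def test_spliced_read_gap_contributes_nothing(self, tmp_path):
        sam = make_sam(
            tmp_path / "r.sam", [("r1", 0, "s1", 0, "50M100N50M")], scaffolds=self.lengths
        )
        track = compute_cpb(sam, self.lengths)
        assert track.depth["s1"][:50].tolist() == [1] * 50
        assert track.depth["s1"][50:150].sum() == 0
        assert track.depth["s1"][150:200].tolist() == [1] * 50

    def test_matches_naive_per_base_oracle(self, tmp_path):
        rng = np.random.default_rng(5)
        records, oracle = [], {s: np.zeros(n, dtype=int) for s, n in self.lengths.items()}
        for i in range(1000):
            scaffold = "s1" if rng.random() < 0.5 else "s2"
            pos = int(rng.integers(0, 1500))
            if rng.random() < 0.3:
                m1, gap, m2 = (int(rng.integers(20, 60)) for _ in range(3))
                cigar = f"{m1}M{gap}N{m2}M"
                blocks = [(pos, pos + m1), (pos + m1 + gap, pos + m1 + gap + m2)]
            else:
                m = int(rng.integers(30, 120))
                cigar, blocks = f"{m}M", [(pos, pos + m)]
            records.append((f"r{i}", 0, scaffold, pos, cigar))
            for s, e in blocks:
                for b in range(s, min(e, self.lengths[scaffold])):
                    oracle[scaffold][b] += 1
        sam = make_sam(tmp_path / "r.sam", records, scaffolds=self.lengths)
        track = compute_cpb(sam, self.lengths)
        for scaffold in self.lengths:
            assert np.array_equal(track.depth[scaffold], oracle[scaffold])

    def test_secondary_and_unmapped_reads_ignored(self, tmp_path):
        sam = make_sam(
            tmp_path / "r.sam",
            [("r1", 0, "s1", 0, "50M"), ("r1", 256, "s1", 500, "50M"), ("r2", 4, None, 0, None)],
            scaffolds=self.lengths,
        )
        track = compute_cpb(sam, self.lengths)
        assert track.depth["s1"][500:550].sum() == 0

    def test_bedgraph_round_trip(self, tmp_path):
        track = CoverageTrack({"s1": np.array([0, 2, 2, 5, 0, 0, 1], dtype=np.int64)})
        path = tmp_path / "cov.bedgraph"
        track.to_bedgraph(path)
        back = CoverageTrack.from_bedgraph(path, {"s1": 7})
        assert np.array_equal(back.depth["s1"], track.depth["s1"])


class TestLowCoverageFilter:
    @pytest.mark.parametrize("max_depth, verdict", [(49, DROP), (50, KEEP), (0, DROP)])
    def test_strictly_below_threshold_drops(self, max_depth, verdict):
        depth = np.zeros(500, dtype=np.int64)
        depth[200] = max_depth
        track = CoverageTrack({"s1": depth})
        assert low_coverage_filter(chain([(100, 400)]), track, threshold=50) == verdict

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        track = CoverageTrack({"s1": rng.integers(0, 100, size=5000)})
        pts = [
            chain([(int(s), int(s) + 200)], pt_id=f"p{i}")
            for i, s in enumerate(rng.integers(0, 4800, size=100))
        ]
        kept = [
            sum(low_coverage_filter(p, track, threshold=t) == KEEP for p in pts)
            for t in range(0, 120, 10)
        ]
        assert kept == sorted(kept, reverse=True)


def test_junction_tsv_dialects(tmp_path):
    native = tmp_path / "j.tsv"
    native.write_text("scaffold\tintron_start\tintron_end\tsupport\ns1\t100\t500\t4\n")
    assert read_junction_tsv(native) == [(("s1", 100, 500), 4)]
    star = tmp_path / "SJ.out.tab"
    star.write_text("s1\t101\t500\t1\t1\t0\t4\t0\t20\n")
    assert read_junction_tsv(star, dialect="star") == [(("s1", 100, 500), 4)]
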