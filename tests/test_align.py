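"""Alignment verification: anchors, window filter, realignment, GT/AG."""

import numpy as np
import pytest

from rocirc.align import (
    AlignedSegment,
    GenomeIndex,
    SplitAlignment,
    VerifyParams,
    adjust_gt_ag,
    align_read_internal,
    classify_full_length,
    filter_linear,
    local_realign,
    map_candidates,
    parse_sam_segments,
    select_anchor,
    verify_merged_read,
    window_filter,
)
from rocirc.io import revcomp
from rocirc.rodetect import ReadPair, detect_ro_pairs
from rocirc.simulate import SimConfig, simulate_dataset


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def two_exon_locus():
    """chrA with exons 501-620 and 771-940, canonical splice signals."""
    rng = np.random.default_rng(77)
    seq = list("".join(rng.choice(list("ACGT"), size=1500)))
    seq[497:499] = "AG"  # upstream of the BSJ acceptor (1-based 498-499)
    seq[620:622] = "GT"  # intron start after exon1 (1-based 621-622)
    seq[768:770] = "AG"  # intron end before exon2 (1-based 769-770)
    seq[940:942] = "GT"  # downstream of the BSJ donor (1-based 941-942)
    # avoid a spurious GT right at the exon1 terminus (keeps shifts unique)
    if seq[618] == "G" and seq[619] == "T":
        seq[619] = "A"
    genome = {"chrA": "".join(seq)}
    exons = [(501, 620), (771, 940)]
    circle = genome["chrA"][500:620] + genome["chrA"][770:940]
    return genome, exons, circle


def _seg(rs, re_, ref_s, ref_e, chrom="chrA", strand="+", score=None, mapq=60):
    return AlignedSegment(
        read_start=rs,
        read_end=re_,
        chrom=chrom,
        ref_start=ref_s,
        ref_end=ref_e,
        strand=strand,
        score=score if score is not None else (re_ - rs),
        mapq=mapq,
    )


class TestInternalAligner:
    def test_unique_exact_match_single_segment(self, two_exon_locus):
        genome, _exons, _circle = two_exon_locus
        read = genome["chrA"][200:585]  # 385 bases, unique locus
        segs = align_read_internal(read, GenomeIndex(genome))
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.read_start, seg.read_end) == (0, 385)
        assert (seg.ref_start, seg.ref_end) == (201, 585)
        assert seg.strand == "+" and seg.mapq == 60

    def test_minus_strand_match_reported_in_read_frame(self, two_exon_locus):
        genome, _e, _c = two_exon_locus
        read = revcomp(genome["chrA"][300:500])
        segs = align_read_internal(read, GenomeIndex(genome))
        assert len(segs) == 1
        assert segs[0].strand == "-"
        assert (segs[0].ref_start, segs[0].ref_end) == (301, 500)
        assert (segs[0].read_start, segs[0].read_end) == (0, 200)

    def test_split_read_from_two_exon_circle(self, two_exon_locus):
        genome, exons, circle = two_exon_locus
        # walk crossing the back-splice junction: genomic order inverted
        walk = circle[150:] + circle[:100]  # exon2 tail then exon1 head
        segs = align_read_internal(walk, GenomeIndex(genome))
        segs = sorted(segs, key=lambda s: s.read_start)
        assert len(segs) == 2
        assert segs[0].ref_start > segs[1].ref_start  # inverted order

    def test_low_scoring_segments_absent(self, two_exon_locus):
        genome, _e, _c = two_exon_locus
        read = genome["chrA"][100:118]  # 18 < min_score 19
        assert align_read_internal(read, GenomeIndex(genome)) == []


class TestSelectAnchor:
    def test_low_mapq_long_segment_skipped(self):
        sa = SplitAlignment("r", [_seg(0, 180, 1000, 1179, mapq=10),
                                  _seg(180, 300, 2000, 2119, mapq=60)])
        anchor = select_anchor(sa)
        assert anchor.read_len == 120

    def test_single_qualifying_segment(self):
        sa = SplitAlignment("r", [_seg(0, 100, 1000, 1099)])
        assert select_anchor(sa) is sa.segments[0]

    def test_tie_broken_by_leftmost_genomic_start(self):
        sa = SplitAlignment("r", [_seg(0, 100, 5000, 5099),
                                  _seg(100, 200, 1000, 1099)])
        assert select_anchor(sa).ref_start == 1000

    def test_mapq_threshold_is_strict(self):
        sa = SplitAlignment("r", [_seg(0, 100, 1000, 1099, mapq=15)])
        assert select_anchor(sa) is None


class TestWindowFilter:
    params = VerifyParams()

    def test_nearby_segments_keep_read(self):
        anchor = _seg(0, 100, 1_000_000, 1_000_099)
        other = _seg(100, 160, 1_050_000, 1_050_059)  # 50 kb away
        sa = SplitAlignment("r", [anchor, other])
        assert window_filter(sa, anchor, self.params, read_len=300)  # 160 > 150

    def test_distant_segment_not_counted(self):
        anchor = _seg(0, 120, 1_000_000, 1_000_119)
        far = _seg(120, 240, 1_250_000, 1_250_119)  # 200 kb away
        sa = SplitAlignment("r", [anchor, far])
        assert not window_filter(sa, anchor, self.params, read_len=300)  # 120 <= 150

    def test_full_length_alignment_always_kept(self):
        anchor = _seg(0, 300, 1_000_000, 1_000_299)
        sa = SplitAlignment("r", [anchor])
        assert window_filter(sa, anchor, self.params, read_len=300)


class TestLocalRealign:
    def test_exact_prefix_placed_with_full_score(self, two_exon_locus):
        genome, _e, _c = two_exon_locus
        read = genome["chrA"][100:130] + genome["chrA"][1130:1330]
        sa = SplitAlignment("r", [_seg(30, 230, 1131, 1330)])
        sa.anchor_index = 0
        out = local_realign(read, sa, genome)
        assert out is not None
        placed = [s for s in out.segments if s.read_start == 0]
        assert placed and placed[0].ref_start == 101 and placed[0].score == 30

    def test_prefix_with_one_substitution_scored(self, two_exon_locus):
        genome, _e, _c = two_exon_locus
        prefix = list(genome["chrA"][100:130])
        prefix[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[prefix[10]]
        read = "".join(prefix) + genome["chrA"][1130:1330]
        sa = SplitAlignment("r", [_seg(30, 230, 1131, 1330)])
        sa.anchor_index = 0
        out = local_realign(read, sa, genome)
        assert out is not None
        placed = [s for s in out.segments if s.read_start <= 1]
        # 29 matches - 4 for the mismatch = 25 (oracle: exhaustive placement)
        assert placed and placed[0].score == 25

    def test_foreign_fragment_discards_read(self, two_exon_locus):
        genome, _e, _c = two_exon_locus
        read = _random_seq(40, 999) + genome["chrA"][1130:1330]
        sa = SplitAlignment("r", [_seg(40, 240, 1131, 1330)])
        sa.anchor_index = 0
        assert local_realign(read, sa, genome) is None


class TestAdjustGtAg:
    def test_clean_junction_kept_unchanged(self, two_exon_locus):
        genome, exons, circle = two_exon_locus
        read = circle[60:240]  # spans the forward splice at circle pos 120
        sa = SplitAlignment("r", [_seg(0, 60, 561, 620), _seg(60, 180, 771, 890)])
        out = adjust_gt_ag(read, sa, genome)
        assert out is not None
        assert out.segments[0].ref_end == 620
        assert out.segments[1].ref_start == 771

    def test_misplaced_boundary_shifted_onto_gt_ag(self, two_exon_locus):
        genome, exons, circle = two_exon_locus
        read = circle[60:240]
        # boundary misplaced 2 bases into exon1 (ambiguous repeat scenario)
        sa = SplitAlignment("r", [_seg(0, 58, 561, 618), _seg(58, 180, 769, 890)])
        out = adjust_gt_ag(read, sa, genome)
        assert out is not None
        assert out.segments[0].ref_end == 620
        assert out.segments[1].ref_start == 771

    def test_non_canonical_junction_discarded(self):
        rng = np.random.default_rng(5)
        seq = list("".join(rng.choice(list("ACGT"), size=800)))
        seq[188:212] = "A" * 24  # no GT reachable within the shift range
        seq[200:202] = "GC"  # GC/AG donor: not accepted
        seq[288:312] = "C" * 24
        seq[298:300] = "AG"
        genome = {"chrB": "".join(seq)}
        read = genome["chrB"][150:200] + genome["chrB"][300:400]
        sa = SplitAlignment(
            "r",
            [_seg(0, 50, 151, 200, chrom="chrB"), _seg(50, 150, 301, 400, chrom="chrB")],
        )
        assert adjust_gt_ag(read, sa, genome) is None

    def test_flank_mismatch_discards(self, two_exon_locus):
        genome, exons, circle = two_exon_locus
        read = list(circle[60:240])
        # junction sits at read position 60; corrupt a base in its 5bp flank
        read[57] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[57]]
        sa = SplitAlignment("r", [_seg(0, 60, 561, 620), _seg(60, 180, 771, 890)])
        assert adjust_gt_ag("".join(read), sa, genome) is None


class TestFilterLinear:
    def test_pseudo_adapter_read_dropped(self, two_exon_locus):
        genome, _e, _c = two_exon_locus
        adapter = _random_seq(20, 1234)
        read = adapter + genome["chrA"][1000:1180]
        sa = SplitAlignment("r", [_seg(20, 200, 1001, 1180)])
        sa.anchor_index = 0
        assert not filter_linear(read, sa, 20, genome)

    def test_backspliced_read_kept(self, two_exon_locus):
        genome, _e, _c = two_exon_locus
        read = "N" * 200  # content irrelevant: BSJ presence decides
        sa = SplitAlignment("r", [_seg(0, 100, 771, 870), _seg(100, 200, 501, 600)])
        sa.anchor_index = 0
        assert filter_linear(read, sa, 15, genome)

    def test_colinear_read_with_aligned_ends_kept(self, two_exon_locus):
        # tandem-repeat-like case: the terminal subsequences re-place (here:
        # they are part of the read's own alignment near the anchor)
        genome, _e, _c = two_exon_locus
        read = genome["chrA"][1000:1200]
        sa = SplitAlignment("r", [_seg(0, 200, 1001, 1200)])
        sa.anchor_index = 0
        assert filter_linear(read, sa, 15, genome)


class TestClassify:
    def test_overlapping_ends_full_length(self):
        sa = SplitAlignment("r", [_seg(0, 150, 701, 850),
                                  _seg(150, 350, 501, 700),
                                  _seg(350, 420, 701, 770)])
        assert classify_full_length(sa) == "full_length_3ro"

    def test_disjoint_ends_same_cirexon(self):
        sa = SplitAlignment("r", [_seg(0, 100, 1101, 1200),
                                  _seg(100, 250, 1000, 1149)])
        # back-splice present; both terminal segments inside chr:1000-1400
        sa2 = SplitAlignment("r", [_seg(0, 100, 1201, 1300),
                                   _seg(100, 200, 1000, 1099)])
        assert classify_full_length(sa2, [(1000, 1400)]) == "full_length_same_cirexon"

    def test_ends_in_different_cirexons_reserved(self):
        sa = SplitAlignment("r", [_seg(0, 100, 2001, 2100),
                                  _seg(100, 200, 1000, 1099)])
        assert classify_full_length(sa, [(1000, 1200), (2001, 2200)]) == "reserve"

    def test_single_colinear_segment_is_not_full_length(self):
        sa = SplitAlignment("r", [_seg(0, 200, 1000, 1199)])
        assert classify_full_length(sa, [(900, 1400)]) == "reserve"


class TestLariat:
    def test_intronic_circle_without_backsplice_signal_discarded(self):
        # a lariat-derived circle: the wrap junction has no AG upstream /
        # GT downstream, so GT/AG adjustment must reject every read
        rng = np.random.default_rng(31)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        genome = {"chrL": seq}
        circle = seq[700:1000]  # 300-base intronic circle, no signals
        walk = (circle * 3)[50 : 50 + 385]
        segs = align_read_internal(walk, GenomeIndex(genome))
        sa = SplitAlignment("lariat", segs)
        status, reason, adj, _ = verify_merged_read(walk, sa, 85, genome)
        assert status == "dropped"
        assert reason == "noncanonical"


class TestSamParsing:
    def test_supplementary_softclip_and_reverse(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\n"
            "@SQ\tSN:chr1\tLN:5000\n"
            "r1\t0\tchr1\t101\t60\t60M40S\t*\t0\t0\t" + "A" * 100 + "\t*\tAS:i:60\n"
            "r1\t2064\tchr1\t501\t60\t65H35M\t*\t0\t0\t" + "A" * 35 + "\t*\tAS:i:35\n"
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 50 + "\t*\n"
        )
        segs = parse_sam_segments(str(sam))
        assert set(segs) == {"r1"}
        by_start = sorted(segs["r1"], key=lambda s: (s.read_start, s.read_end))
        s1, s2 = by_start
        assert (s1.read_start, s1.read_end, s1.ref_start, s1.ref_end, s1.strand) == (
            0, 35, 501, 535, "-")
        assert (s2.read_start, s2.read_end, s2.ref_start, s2.ref_end, s2.strand) == (
            0, 60, 101, 160, "+")

    def test_deletion_splits_into_two_segments(self, tmp_path):
        sam = tmp_path / "del.sam"
        sam.write_text(
            "@SQ\tSN:chr1\tLN:5000\n"
            "r1\t0\tchr1\t101\t60\t50M200D50M\t*\t0\t0\t" + "A" * 100 + "\t*\n"
        )
        segs = parse_sam_segments(str(sam))["r1"]
        assert len(segs) == 2
        assert (segs[0].ref_start, segs[0].ref_end) == (101, 150)
        assert (segs[1].ref_start, segs[1].ref_end) == (351, 400)


class TestCleanDataInvariant:
    def test_no_false_drops_on_error_free_reads(self, small_dataset):
        genome = small_dataset.genome
        pairs = [ReadPair(rid, s1, s2) for rid, s1, s2 in small_dataset.pairs]
        merged, _ = detect_ro_pairs(pairs)
        sas = map_candidates(
            {m.read_id: m.sequence for m in merged}, genome, mode="internal"
        )
        for m in merged:
            sa = sas.get(m.read_id)
            assert sa is not None
            status, reason, _adj, _r = verify_merged_read(
                m.sequence, sa, m.ro5_len, genome
            )
            assert status != "dropped", (m.read_id, reason)
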