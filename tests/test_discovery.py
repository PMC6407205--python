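import numpy as np
import pytest

from canerv.discovery import (
    AnchorPair,
    JunctionContig,
    assemble_junction,
    classify_junction,
    cluster_candidates,
    find_anchor_pairs,
    locate_breakpoint_tsd,
    scan_reference_deletions,
)
from canerv.formats import AlignedRead, GenomicInterval, SequenceRecord, revcomp
from canerv.mapping import ReferenceIndex, map_pairs, map_read
from canerv.synthetic import (
    TruthInsertion,
    implant_insertions,
    make_reference,
    random_dna,
    simulate_reads,
)


def _read(qname, chrom, pos, seq, strand="+", mapq=60, proper=False):
    cigar = f"{len(seq)}M" if chrom else "*"
    return AlignedRead(qname, chrom, pos if chrom else -1, strand, cigar,
                       mapq, seq, is_proper_pair=proper)


class TestMapper:
    @pytest.fixture()
    def index(self, genome40):
        return ReferenceIndex([SequenceRecord("chr1", genome40)])

    def test_exact_unique_read_maps_with_max_quality(self, genome40, index):
        hit = map_read(genome40[5000:5100], index)
        assert (hit.chrom, hit.pos, hit.strand, hit.mapq) == ("chr1", 5000, "+", 60)

    def test_reverse_strand(self, genome40, index):
        hit = map_read(revcomp(genome40[7000:7100]), index)
        assert (hit.pos, hit.strand) == (7000, "-")

    def test_foreign_sequence_unmapped(self, index, rng):
        assert map_read(random_dna(rng, 100), index) is None

    def test_duplicated_locus_gets_zero_quality(self, genome40):
        dup = genome40[:2000] + genome40[:2000] + genome40[2000:10000]
        index = ReferenceIndex([SequenceRecord("chr1", dup)])
        hit = map_read(dup[500:600], index)
        assert hit.mapq == 0

    def test_short_read_unmapped(self, index):
        assert map_read("ACGTACGT", index) is None


class TestAnchorPairs:
    def test_ltr_matching_mate_found(self, ltr, genome40):
        reads = [
            _read("p1", "chr1", 100, genome40[100:200]),
            _read("p1", None, -1, ltr[50:150]),
        ]
        anchors = find_anchor_pairs(reads, {"ltr": ltr, "internal": "A" * 500})
        assert len(anchors) == 1 and anchors[0].erv_part == "ltr"
        assert anchors[0].anchor.pos == 100

    def test_internal_matching_mate_classified(self, ltr, rng, genome40):
        internal = random_dna(rng, 2000)
        reads = [
            _read("p1", "chr1", 100, genome40[100:200]),
            _read("p1", None, -1, revcomp(internal[300:400])),
        ]
        anchors = find_anchor_pairs(reads, {"ltr": ltr, "internal": internal})
        assert [a.erv_part for a in anchors] == ["internal"]

    def test_properly_mapped_pair_excluded(self, ltr, genome40):
        reads = [
            _read("p1", "chr1", 100, genome40[100:200]),
            _read("p1", "chr1", 400, genome40[400:500], strand="-"),
        ]
        assert find_anchor_pairs(reads, {"ltr": ltr}) == []

    def test_half_identity_mate_excluded(self, ltr, rng, genome40):
        mate = ltr[:50] + random_dna(rng, 50)  # ~50% identity over full length
        reads = [
            _read("p1", "chr1", 100, genome40[100:200]),
            _read("p1", None, -1, mate),
        ]
        assert find_anchor_pairs(reads, {"ltr": ltr}) == []


class TestClusterCandidates:
    def _anchor(self, pos, seq="A" * 100):
        return AnchorPair(_read(f"q{pos}", "chr1", pos, seq), "ltr", 1.0, 100, seq)

    def test_three_close_anchors_one_candidate(self):
        cands = cluster_candidates([self._anchor(p) for p in (1000, 1080, 1150)])
        assert len(cands) == 1 and cands[0].support_pairs == 3

    def test_single_anchor_no_candidate(self):
        assert cluster_candidates([self._anchor(1000)]) == []

    def test_candidate_near_known_erv_dropped(self):
        known = [GenomicInterval("chr1", 1400, 1900, "CfERVF1_LTR", "+")]
        cands = cluster_candidates(
            [self._anchor(1000), self._anchor(1100)], known, exclusion_bp=500
        )
        assert cands[0].dropped_reason is not None
        far = [GenomicInterval("chr1", 5000, 5500, "CfERVF1_LTR", "+")]
        cands = cluster_candidates(
            [self._anchor(1000), self._anchor(1100)], far, exclusion_bp=500
        )
        assert cands[0].dropped_reason is None


class TestAssembler:
    def test_exact_overlap_merges(self, rng):
        seq = random_dna(rng, 90)
        contigs = assemble_junction([seq[:60], seq[30:]])
        assert contigs == [seq]

    def test_no_overlap_stays_separate(self, rng):
        a, b = random_dna(rng, 60), random_dna(rng, 60)
        assert len(assemble_junction([a, b])) == 2

    def test_overlap_below_identity_not_merged(self, rng):
        seq = random_dna(rng, 85)
        b = list(seq[60 - 25 :])
        for i in (3, 12, 20):  # 3 mismatches in the 25-bp overlap (88%)
            b[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[i]]
        assert len(assemble_junction([seq[:60], "".join(b)])) == 2

    def test_reverse_complement_overlap_merged(self, rng):
        seq = random_dna(rng, 90)
        contigs = assemble_junction([seq[:60], revcomp(seq[30:])])
        assert contigs in ([seq], [revcomp(seq)])

    def test_order_invariant_for_unique_overlaps(self, rng):
        seq = random_dna(rng, 280)
        reads = [seq[i : i + 80] for i in range(0, 201, 40)]
        baseline = assemble_junction(reads)
        assert baseline == [seq]
        for _ in range(5):
            shuffled = list(rng.permutation(reads))
            assert assemble_junction(shuffled) == baseline

    def test_majority_consensus_corrects_errors(self, rng):
        seq = random_dna(rng, 150)
        reads = [seq[:100], seq[25:125], seq[50:150]]
        bad = list(seq[25:125])
        bad[50] = {"A": "C", "C": "A", "G": "T", "T": "G"}[bad[50]]
        contigs = assemble_junction(reads + ["".join(bad)])
        assert contigs == [seq]


class TestClassifyJunction:
    def test_full_ltr_with_flanks(self, ltr, rng):
        contig = random_dna(rng, 40) + ltr + random_dna(rng, 40)
        j = classify_junction(contig, ltr)
        assert j.side == "full_ltr"
        assert j.ltr_span == (40, 40 + 457)
        assert j.genomic_span == (0, 40) and j.right_genomic_span == (497, 537)

    def test_five_prime_junction(self, ltr, rng):
        j = classify_junction(random_dna(rng, 35) + ltr[:50], ltr)
        assert j.side == "five_prime" and j.genomic_span == (0, 35)

    def test_three_prime_junction(self, ltr, rng):
        j = classify_junction(ltr[-60:] + random_dna(rng, 45), ltr)
        assert j.side == "three_prime" and j.genomic_span == (60, 105)

    def test_reverse_complement_contig_normalized(self, ltr, rng):
        contig = revcomp(random_dna(rng, 35) + ltr[:60])
        j = classify_junction(contig, ltr)
        assert j.side == "five_prime"

    def test_short_genomic_span_rejected(self, ltr, rng):
        assert isinstance(classify_junction(random_dna(rng, 25) + ltr[:100], ltr), str)

    def test_pure_genomic_and_pure_ltr_rejected(self, ltr, rng):
        assert isinstance(classify_junction(random_dna(rng, 120), ltr), str)
        assert isinstance(classify_junction(ltr[:120], ltr), str)


class TestBreakpointTsd:
    @pytest.fixture()
    def setting(self, ltr):
        ref = make_reference(21, [20_000])
        b = 9_000
        tsd = ref[0].seq[b : b + 5]
        return ref, b, tsd

    def _junctions_for(self, ref, element, b, ltr, flank=80):
        occupied = implant_insertions(
            ref, [TruthInsertion("L", "chr1", b, "+", "solo_ltr",
                                 ref[0].seq[b : b + 5], element)]
        )[0].seq
        contig = occupied[b + 5 - flank : b + 5 + len(element) + 5 + flank]
        return classify_junction(contig, ltr)

    def test_implant_round_trip_recovers_breakpoint_and_tsd(self, setting, ltr):
        ref, b, tsd = setting
        j = self._junctions_for(ref, ltr, b, ltr)
        index = ReferenceIndex(ref)
        chrom, bp, found_tsd, orient, flags, sides = locate_breakpoint_tsd(
            [j], index, ltr
        )
        assert (chrom, bp, found_tsd, orient) == ("chr1", b, tsd, "+")

    def test_reverse_orientation_detected(self, setting, ltr):
        ref, b, tsd = setting
        occupied = implant_insertions(
            ref, [TruthInsertion("L", "chr1", b, "-", "solo_ltr", tsd, ltr)]
        )[0].seq
        contig = occupied[b - 80 : b + 5 + 457 + 5 + 80]
        j = classify_junction(contig, ltr)
        index = ReferenceIndex(ref)
        chrom, bp, found_tsd, orient, flags, sides = locate_breakpoint_tsd(
            [j], index, ltr
        )
        assert (bp, found_tsd, orient) == (b, tsd, "-")

    def test_single_five_prime_junction_no_tsd(self, setting, ltr):
        ref, b, tsd = setting
        occupied = implant_insertions(
            ref, [TruthInsertion("L", "chr1", b, "+", "solo_ltr", tsd, ltr)]
        )[0].seq
        contig = occupied[b + 5 - 80 : b + 5 + 60]  # genome + LTR 5' start only
        j = classify_junction(contig, ltr)
        assert j.side == "five_prime"
        index = ReferenceIndex(ref)
        chrom, bp, found_tsd, orient, flags, sides = locate_breakpoint_tsd(
            [j], index, ltr
        )
        assert found_tsd is None and bp == b

    def test_mismatched_duplication_flagged(self, setting, ltr):
        ref, b, tsd = setting
        # occupied allele whose right TSD copy is shifted: duplication absent
        left = ref[0].seq[: b + 5]
        right = ref[0].seq[b + 5 :]  # no duplicated 5-mer
        occupied = left + ltr + right
        contig = occupied[b + 5 - 80 : b + 5 + 457 + 80]
        j = classify_junction(contig, ltr)
        index = ReferenceIndex(ref)
        result = locate_breakpoint_tsd([j], index, ltr)
        assert result is not None
        _, _, found_tsd, _, flags, _ = result
        assert found_tsd is None and "tsd_mismatch" in flags


@pytest.fixture(scope="module")
def scenario():
    """A reference carrying a solo LTR that one haplotype has excised."""
    base = make_reference(31, [30_000])[0].seq
    b = 15_000
    ltr = random_dna(np.random.default_rng(32), 457)
    ref = [SequenceRecord("chr1", base[: b + 5] + ltr + base[b:])]
    excision = [SequenceRecord("chr1", base)]
    index = ReferenceIndex(ref)
    known = [GenomicInterval("chr1", b + 5, b + 5 + 457, "CfERVF1_LTR", "+")]
    return ref, excision, index, known


class TestReferenceDeletionScan:
    def test_excision_haplotype_yields_solo_ltr_call(self, scenario):
        ref, excision, index, known = scenario
        pairs = simulate_reads((excision, excision), 15, base_error=0.0, seed=11)
        calls = scan_reference_deletions(map_pairs(pairs, index), known)
        assert len(calls) == 1
        assert calls[0].size_class == "solo_ltr"
        assert 400 <= calls[0].size <= 500

    def test_no_insert_deviation_no_calls(self, scenario):
        ref, excision, index, known = scenario
        pairs = simulate_reads((ref, ref), 15, base_error=0.0, seed=12)
        assert scan_reference_deletions(map_pairs(pairs, index), known) == []

    def test_low_mapq_supports_ignored(self, scenario):
        ref, excision, index, known = scenario
        pairs = simulate_reads((excision, excision), 15, base_error=0.0, seed=13)
        alns = map_pairs(pairs, index)
        for r in alns:
            r.mapq = min(r.mapq, 10)
        assert scan_reference_deletions(alns, known) == []

    def test_too_few_pairs_for_distribution_error(self, scenario):
        ref, excision, index, known = scenario
        pairs = simulate_reads((excision, excision), 1, base_error=0.0, seed=14)
        with pytest.raises(ValueError, match="proper pairs"):
            scan_reference_deletions(map_pairs(pairs, index)[:100], known)

    def test_call_not_intersecting_known_erv_dropped(self, scenario):
        ref, excision, index, _known = scenario
        pairs = simulate_reads((excision, excision), 15, base_error=0.0, seed=11)
        elsewhere = [GenomicInterval("chr1", 100, 600, "CfERVF1_LTR", "+")]
        assert scan_reference_deletions(map_pairs(pairs, index), elsewhere) == []
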