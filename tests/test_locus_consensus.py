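"""Locus merging semantics, reduced-reference extraction, pileup consensus."""

import numpy as np
import pytest

from prolamin_scan.io_core import GenomicInterval, SeqRecord
from prolamin_scan.locus_consensus import (ConsensusSequence,
                                           anchor_read_to_reference,
                                           call_consensus,
                                           extract_reduced_reference,
                                           merge_loci)
from prolamin_scan.mapping import AlignmentRecord


def _aln(chrom, start, end, read_id="r"):
    return AlignmentRecord(read_id, GenomicInterval(chrom, start, end, "+"),
                           (0, end - start), 10, 1.0, True)


class TestMergeLoci:
    def test_hand_merge(self):
        alns = [_aln("chr1", 100, 200), _aln("chr1", 150, 300),
                _aln("chr1", 400, 500)]
        loci = merge_loci(alns, min_reads=1)
        assert [(l.interval.start, l.interval.end) for l in loci] == \
               [(100, 300), (400, 500)]

    def test_book_ended_intervals_merge(self):
        loci = merge_loci([_aln("chr1", 100, 200), _aln("chr1", 200, 300)],
                          min_reads=1)
        assert [(l.interval.start, l.interval.end) for l in loci] == [(100, 300)]

    def test_support_filter_and_counts(self):
        alns = [_aln("chr1", 0, 100) for _ in range(3)] + \
               [_aln("chr1", 500, 600)]
        loci = merge_loci(alns, min_reads=2)
        assert len(loci) == 1 and loci[0].n_supporting_reads == 3

    def test_idempotent_disjoint_sorted(self):
        rng = np.random.default_rng(5)
        alns = [_aln(f"chr{rng.integers(2)}", s := int(rng.integers(1000)),
                     s + int(rng.integers(1, 200))) for _ in range(200)]
        loci = merge_loci(alns, min_reads=1)
        ivs = [l.interval for l in loci]
        assert ivs == sorted(ivs, key=lambda i: (i.chromosome, i.start))
        for a, b in zip(ivs, ivs[1:]):
            if a.chromosome == b.chromosome:
                assert a.end < b.start   # disjoint, not even book-ended
        again = merge_loci(
            [_aln(i.chromosome, i.start, i.end) for i in ivs], min_reads=1)
        assert [(l.interval.start, l.interval.end) for l in again] == \
               [(i.start, i.end) for i in ivs]
        # total covered bases never increases under merging
        assert sum(len(i) for i in ivs) <= \
               sum(a.target.end - a.target.start for a in alns)

    def test_locus_id_format(self):
        (locus,) = merge_loci([_aln("chr3D", 479, 600)], min_reads=1)
        assert locus.locus_id == "chr3D-479"


class TestReducedReference:
    GENOME = [SeqRecord("chr1D", "ACGT" * 100)]

    def _locus(self, start, end):
        from prolamin_scan.locus_consensus import Locus
        return Locus(f"chr1D-{start}", GenomicInterval("chr1D", start, end), 5)

    def test_no_flank(self):
        (rec,) = extract_reduced_reference(self.GENOME, [self._locus(100, 200)],
                                           flank=0)
        assert rec.id == "chr1D-100"
        assert rec.sequence == self.GENOME[0].sequence[100:200]

    def test_flank_clipped_at_start(self):
        (rec,) = extract_reduced_reference(self.GENOME, [self._locus(0, 80)],
                                           flank=50)
        assert len(rec.sequence) == 130

    def test_locus_beyond_end_errors(self):
        with pytest.raises(ValueError):
            extract_reduced_reference(self.GENOME, [self._locus(350, 450)])


class TestCallConsensus:
    REF = SeqRecord("locus", "ACGTACGTACGTACGTACGT")

    def test_majority_overrides_reference(self):
        # column 2 (ref G): 5 reads say A, 1 says C
        placements = [[(2, "A")]] * 5 + [[(2, "C")]]
        cons = call_consensus(placements, self.REF, min_depth=3)
        assert cons.sequence[2] == "A"
        assert (2, "G", "A", 5 / 6) in cons.variants

    def test_tie_resolves_to_reference(self):
        placements = [[(2, "A")]] * 3 + [[(2, "G")]] * 3
        cons = call_consensus(placements, self.REF, min_depth=3)
        assert cons.sequence[2] == "G"

    def test_below_min_depth_emits_reference(self):
        cons = call_consensus([[(2, "A")], [(2, "A")]], self.REF, min_depth=3)
        assert cons.sequence == self.REF.sequence
        assert cons.variants == []

    def test_no_reads_low_confidence(self):
        cons = call_consensus([], self.REF)
        assert cons.sequence == self.REF.sequence
        assert cons.low_confidence

    def test_minor_allele_recorded(self):
        placements = [[(2, "G")]] * 7 + [[(2, "T")]] * 3
        cons = call_consensus(placements, self.REF, min_alt_fraction=0.2)
        assert cons.sequence[2] == "G"
        assert (2, "G", "T", 0.3) in cons.variants


class TestAnchorPlacement:
    def test_exact_read_places_all_bases(self):
        rng = np.random.default_rng(9)
        ref = "".join(rng.choice(list("ACGT"), size=400))
        read = ref[50:350]
        placements = anchor_read_to_reference(read, ref)
        assert placements == [(50 + i, read[i]) for i in range(len(read))]

    def test_intron_spanning_read(self):
        rng = np.random.default_rng(10)
        exon1 = "".join(rng.choice(list("ACGT"), size=150))
        exon2 = "".join(rng.choice(list("ACGT"), size=150))
        intron = "GT" + "".join(rng.choice(list("ACGT"), size=100)) + "AG"
        ref = exon1 + intron + exon2
        read = exon1 + exon2          # spliced
        placements = dict(anchor_read_to_reference(read, ref))
        for i in range(150):
            assert placements[i] == exon1[i]
            assert placements[len(exon1) + len(intron) + i] == exon2[i]
        # intron interior receives no read bases; junction-edge ambiguity
        # (identical flanking bases) may place a base that matches anyway
        for pos, base in placements.items():
            if 150 <= pos < 254:
                assert pos in (150, 151, 252, 253)
                assert base == ref[pos]

    def test_foreign_termini_not_placed(self):
        rng = np.random.default_rng(11)
        ref = "".join(rng.choice(list("ACGT"), size=300))
        read = "GACTGCGTACC" + ref[20:280] + "A" * 20
        placements = anchor_read_to_reference(read, ref)
        positions = [pos for pos, _ in placements]
        assert min(positions) >= 20 and max(positions) < 280
        assert all(ref[pos] == base for pos, base in placements)
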