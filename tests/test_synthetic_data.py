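"""Generator: planted truth, determinism, transcripts and read noise."""

from collections import Counter

import pytest

from prolamin_scan import families as fam
from prolamin_scan.epitope_analysis import scan_epitopes
from prolamin_scan.io_core import format_fasta, reverse_complement
from prolamin_scan.synthetic_data import (GenomeModel, ReadSimConfig,
                                          VarietyProfile, build_genome,
                                          default_genome_model,
                                          default_profile, simulate_reads,
                                          simulate_transcripts)


class TestBuildGenome:
    def test_default_avenin_counts(self, truth):
        counts = Counter(row.family for row in truth.loci)
        assert counts["avenin-A"] == 3
        assert counts["avenin-B"] == 3
        assert counts["avenin-C1"] == 3
        assert counts["avenin-C2"] == 5
        assert counts["avenin-D"] == 3
        assert counts["fragment"] == 3
        assert counts["promoter"] == 1

    def test_reduced_b_profile(self):
        _, truth = build_genome(
            profile=default_profile("Ebene", absent_b_on_3d=True), seed=1)
        assert truth.gene_inventory()["avenin-B"] == 2

    def test_same_seed_byte_identical(self, genome):
        again, _ = build_genome(seed=1)
        assert format_fasta(again) == format_fasta(genome)

    def test_unknown_absent_gene_named_in_error(self):
        profile = VarietyProfile("x", frozenset({"chr9Z.avenin-B.1"}))
        with pytest.raises(ValueError, match="chr9Z.avenin-B.1"):
            build_genome(profile=profile, seed=0)

    def test_intervals_within_bounds_and_disjoint(self, truth):
        model = default_genome_model()
        by_chrom: dict[str, list] = {}
        for row in truth.loci:
            iv = row.interval
            assert 0 <= iv.start < iv.end <= model.chromosome_length(iv.chromosome)
            by_chrom.setdefault(iv.chromosome, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start

    def test_pseudogene_planting(self):
        model = default_genome_model()
        model = GenomeModel(model.chromosomes, model.cassettes,
                            pseudogenize=frozenset({"chr1D.avenin-A.1"}))
        _, truth = build_genome(model, seed=2)
        row = next(r for r in truth.loci if r.gene_id == "chr1D.avenin-A.1")
        assert row.status == "pseudogene"
        assert "*" not in row.protein  # truncated product
        # pseudogenes drop out of the haploid inventory
        assert truth.gene_inventory()["avenin-A"] == 2


class TestEpitopeTruth:
    @pytest.mark.parametrize("repeats,expected_g9b", [(2, 10), (3, 15)])
    def test_planted_epitope_recount(self, repeats, expected_g9b):
        _, truth = build_genome(
            profile=default_profile(c2_repeat_count=repeats), seed=1)
        recount: Counter = Counter()
        for row in truth.loci:
            if row.status != "whole" or not row.family.startswith("avenin"):
                continue
            for m in scan_epitopes(row.protein):
                recount[m.epitope] += 1
        assert dict(recount) == truth.epitope_counts
        assert truth.epitope_counts["Av-gamma9B"] == expected_g9b

    @pytest.mark.parametrize("repeats", [2, 3])
    def test_c2_count_times_repeats(self, repeats):
        _, truth = build_genome(
            profile=default_profile(c2_repeat_count=repeats), seed=1)
        n_c2 = truth.gene_inventory()["avenin-C2"]
        assert n_c2 * repeats == truth.epitope_counts["Av-gamma9B"]


class TestTranscripts:
    def test_globulin_introns_removed(self, genome, truth, transcripts):
        by_id = {t.id: t for t in transcripts}
        by_name = {r.id: r.sequence for r in genome}
        for row in truth.loci:
            if not row.family.startswith("globulin"):
                continue
            tx = by_id[f"{row.gene_id}.mRNA"]
            genomic = by_name[row.interval.chromosome][
                row.interval.start:row.interval.end]
            intron_total = sum(e - s for s, e in row.introns)
            assert len(row.introns) == 3
            for s, e in row.introns:
                assert 104 <= e - s <= 137
                assert genomic[s:e] not in tx.sequence
            from prolamin_scan.synthetic_data import TRANSCRIPT_3P, TRANSCRIPT_5P
            assert len(tx) == (len(TRANSCRIPT_5P) + len(genomic)
                               - intron_total + len(TRANSCRIPT_3P))

    def test_avenin_transcripts_carry_probe_motif(self, truth, transcripts):
        from prolamin_scan.io_core import degenerate_match
        by_id = {t.id: t for t in transcripts}
        for row in truth.loci:
            if row.family.startswith("avenin") and row.status == "whole":
                tx = by_id[f"{row.gene_id}.mRNA"]
                assert degenerate_match(fam.AVENIN_PROBE_TAIL, tx.sequence)

    def test_pseudogene_transcribed(self):
        model = default_genome_model()
        model = GenomeModel(model.chromosomes, model.cassettes,
                            pseudogenize=frozenset({"chr1D.avenin-A.1"}))
        genome, truth = build_genome(model, seed=2)
        tx = simulate_transcripts(genome, truth)
        assert any(t.id == "chr1D.avenin-A.1.mRNA" for t in tx)


class TestReads:
    def test_zero_noise_reads_are_substrings(self, transcripts):
        reads = simulate_reads(transcripts, ReadSimConfig(50, seed=3))
        pool = {t.id: t.sequence for t in transcripts}
        for read in reads:
            src = read.description.split()[0].split("=")[1]
            strand = read.description.split("strand=")[1]
            seq = read.sequence if strand == "+" else \
                reverse_complement(read.sequence)
            assert seq in pool[src]

    def test_determinism(self, transcripts):
        from prolamin_scan.io_core import format_fastq
        cfg = ReadSimConfig(1000, substitution_rate=0.03, insertion_rate=0.01,
                            deletion_rate=0.01, seed=9)
        a = format_fastq(simulate_reads(transcripts, cfg))
        b = format_fastq(simulate_reads(transcripts, cfg))
        assert a == b

    def test_substitution_rate_recovered(self, transcripts):
        cfg = ReadSimConfig(20, mean_length=2000, substitution_rate=0.05,
                            seed=4)
        reads = simulate_reads(transcripts, cfg)
        pool = {t.id: t.sequence for t in transcripts}
        mismatches = total = 0
        for read in reads:
            fields = dict(part.split("=") for part in read.description.split())
            seq = read.sequence if fields["strand"] == "+" else \
                reverse_complement(read.sequence)
            source = pool[fields["src"]][int(fields["start"]):int(fields["end"])]
            assert len(seq) == len(source)
            mismatches += sum(1 for x, y in zip(seq, source) if x != y)
            total += len(seq)
        assert total >= 10_000
        assert abs(mismatches / total - 0.05) <= 0.01

    def test_empty_transcripts_error(self):
        with pytest.raises(ValueError):
            simulate_reads([], ReadSimConfig(10, seed=0))

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            ReadSimConfig(10, substitution_rate=0.5)
        with pytest.raises(ValueError):
            ReadSimConfig(0)
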