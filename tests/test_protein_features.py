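"""Status calling, domain segmentation, composition tables and summaries."""

from collections import Counter

import pytest

from prolamin_scan import families as fam
from prolamin_scan.locus_consensus import ConsensusSequence
from prolamin_scan.protein_features import (call_gene, composition_table,
                                            count_cysteines,
                                            load_published_composition,
                                            segment_avenin,
                                            summarize_composition)


def _cons(seq, depth=10):
    return ConsensusSequence.from_sequence("locus", seq, depth)


class TestCallGene:
    def test_internal_stop_is_pseudogene(self):
        cds = fam.avenin_cds("avenin-B")          # 220 codons incl. stop
        broken = cds[:150] + "TAA" + cds[153:]    # stop at codon 50
        assert call_gene(_cons(broken)).status == "pseudogene"

    def test_clean_orf_is_whole(self):
        protein = ("M" + "AVSTG" * 44 + "A")      # 222 residues
        cds = fam.reverse_translate(protein) + "TAA"   # 669 nt
        call = call_gene(_cons(cds))
        assert call.status == "whole"
        assert len(call.protein) == 222

    def test_short_consensus_is_fragment(self):
        assert call_gene(_cons(fam.avenin_cds("avenin-B")[:150])).status == \
            "fragment"

    def test_no_start_codon_is_fragment(self):
        assert call_gene(_cons(fam.PROMOTER_SEQ)).status == "fragment"

    def test_uncovered_flanks_ignored(self):
        cds = fam.avenin_cds("avenin-C2")
        seq = "ATGATT" * 20 + cds + "G" * 40     # decoy ATGs in dead flank
        cons = ConsensusSequence.from_sequence("locus", seq, 0)
        cons.depth[120:120 + len(cds)] = [20] * len(cds)
        call = call_gene(cons)
        assert call.status == "whole"
        assert call.protein == fam.avenin_protein("avenin-C2")[0]

    def test_globulin_genomic_consensus_is_whole(self):
        genomic, _ = fam.globulin_genomic_cds("globulin-B", 0)
        assert call_gene(_cons(genomic)).status == "whole"


class TestCysteines:
    def test_family_census(self):
        assert count_cysteines(fam.avenin_protein("avenin-B")[0]) == 8
        assert count_cysteines(fam.avenin_protein("avenin-A")[0]) == 9

    def test_none(self):
        assert count_cysteines("PQPQ") == 0
        with pytest.raises(ValueError):
            count_cysteines("")


class TestSegmentAvenin:
    @pytest.mark.parametrize("family", fam.AVENIN_FAMILIES)
    def test_truth_boundaries_within_3(self, family):
        protein, bounds = fam.avenin_protein(family)
        domains = segment_avenin(protein)
        assert not domains.failed
        for name, (s, e) in bounds.items():
            ds, de = domains.segments[name]
            assert abs(ds - s) <= 3 and abs(de - e) <= 3, (family, name)

    def test_signal_peptide_fixed(self):
        protein, _ = fam.avenin_protein("avenin-A")
        assert segment_avenin(protein).segments["signal_peptide"] == (0, 19)

    def test_degenerate_repeat_protein_flags_failure(self):
        assert segment_avenin("M" * 19 + "PQ" * 60).failed

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            segment_avenin("MKTF" * 10)


class TestComposition:
    def test_simple(self):
        table = composition_table([("x", "PPQQ")])
        assert table.loc["P", "x"] == 50.0
        assert table.loc["Q", "x"] == 50.0
        assert table.loc["total", "x"] == 4

    def test_uniform(self):
        table = composition_table([("x", "ACDEFGHIKLMNPQRSTVWY")])
        assert all(table.loc[aa, "x"] == 5.0 for aa in "ACDEFGHIKLMNPQRSTVWY")

    def test_generator_protein_matches_recount(self):
        protein, _ = fam.avenin_protein("avenin-C2")
        table = composition_table([("c2", protein)])
        counts = Counter(protein)
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            expected = round(100 * counts.get(aa, 0) / len(protein), 2)
            assert table.loc[aa, "c2"] == pytest.approx(expected, abs=0.005)
        assert table.loc["total", "c2"] == len(protein)

    def test_columns_sum_to_100(self):
        proteins = [(f, fam.avenin_protein(f)[0]) for f in fam.AVENIN_FAMILIES]
        table = composition_table(proteins)
        sums = table.drop(index="total").sum()
        assert ((sums - 100).abs() <= 0.05).all()

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            composition_table([("x", "")])


@pytest.fixture(scope="module")
def published():
    return load_published_composition()


class TestSummarize:
    def test_published_column_sums(self, published):
        sums = published.drop(index="total").sum()
        assert ((sums - 100).abs() <= 0.05).all()

    def test_published_aggregates(self, published):
        non_d = [c for c in published.columns if not c.startswith("D.")]
        groups = {"non-D": non_d,
                  "A": ["A.1D", "A.3D", "A.Un"],
                  "C1": ["C1.1D", "C1.3D", "C1.UN"]}
        summary = summarize_composition(published, groups)
        assert summary.cell("non-D", "Q")[:2] == (24.1, 34.9)
        assert summary.cell("non-D", "P")[1] == 11.0
        assert summary.cell("C1", "L")[:2] == (15.3, 17.4)
        assert summary.cell("A", "Q")[2] == 25.81
        assert summary.mean_length == 223

    def test_single_column_min_eq_max_eq_mean(self, published):
        summary = summarize_composition(published, {"one": ["A.1D"]})
        for aa in "APQL":
            lo, hi, mean = summary.cell("one", aa)
            # min/max print at 1 decimal, the mean at 2: equal up to rounding
            assert lo == hi
            assert round(mean, 1) == pytest.approx(lo, abs=0.05)

    def test_min_le_mean_le_max(self, published):
        summary = summarize_composition(
            published, {"all": list(published.columns)})
        table = summary.table
        # 1-decimal min/max bracket the 2-decimal mean up to rounding slack
        assert ((table["min"] - 0.05) <= table["mean"]).all()
        assert (table["mean"] <= (table["max"] + 0.05)).all()

    def test_unknown_group_column(self, published):
        with pytest.raises(ValueError, match="unknown group"):
            summarize_composition(published, {"bad": ["Z.9X"]})
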