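"""JC distances, alignment optimality, neighbor-joining, family assignment."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from prolamin_scan import families as fam
from prolamin_scan.io_core import SeqRecord
from prolamin_scan.phylo import (DistanceMatrix, JCSaturationError,
                                 assign_family, jc_distance, nj_tree,
                                 pairwise_align)


class TestJCDistance:
    def test_identical(self):
        assert jc_distance("A" * 100, "A" * 100) == 0.0

    def test_closed_form_p_01(self):
        a = "A" * 100
        b = "A" * 90 + "C" * 10
        assert jc_distance(a, b) == pytest.approx(0.107326, abs=1e-6)

    def test_saturation(self):
        with pytest.raises(JCSaturationError):
            jc_distance("AAAA", "ACCC")   # p = 0.75

    def test_gap_columns_excluded(self):
        assert jc_distance("AC-T", "ACGT") == 0.0
        with pytest.raises(ValueError):
            jc_distance("----", "ACGT")

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=60))
            b = "".join(rng.choice(list("ACGT-"), size=60))
            try:
                assert jc_distance(a, b) == jc_distance(b, a)
            except (JCSaturationError, ValueError):
                pass


def _brute_force_alignment_score(a, b, match=1, mismatch=-1, gap=-2):
    """Exhaustive recursion over all global alignments (tiny inputs only)."""
    if not a:
        return gap * len(b)
    if not b:
        return gap * len(a)
    return max(
        _brute_force_alignment_score(a[1:], b[1:]) +
        (match if a[0] == b[0] else mismatch),
        _brute_force_alignment_score(a[1:], b) + gap,
        _brute_force_alignment_score(a, b[1:]) + gap,
    )


def _score(x, y, match=1, mismatch=-1, gap=-2):
    score = 0
    for p, q in zip(x, y):
        if "-" in (p, q):
            score += gap
        else:
            score += match if p == q else mismatch
    return score


class TestPairwiseAlign:
    def test_identity(self):
        x, y = pairwise_align("ACGT", "ACGT")
        assert x == y == "ACGT"
        assert _score(x, y) == 4

    @pytest.mark.parametrize("a,b", [
        ("ACGT", "AGT"), ("ACGTAC", "ACTAC"), ("AAAA", "AATA"),
        ("ACGTACGT", "TACG"), ("GATTACA", "GCATGCA"),
    ])
    def test_optimal_vs_exhaustive(self, a, b):
        x, y = pairwise_align(a, b)
        assert x.replace("-", "") == a and y.replace("-", "") == b
        assert _score(x, y) == _brute_force_alignment_score(a, b)

    def test_swap_symmetry(self):
        x, y = pairwise_align("ACGT", "AGT")
        y2, x2 = pairwise_align("AGT", "ACGT")
        assert _score(x, y) == _score(x2, y2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_align("", "ACGT")


def _path_lengths(newick, labels):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return {(a, b): pdm.distance(taxa[a], taxa[b])
            for a, b in itertools.combinations(labels, 2)}


class TestNJ:
    def test_additive_four_taxon(self):
        d = np.array([[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
                     dtype=float)
        dm = DistanceMatrix(["A", "B", "C", "D"], d)
        paths = _path_lengths(nj_tree(dm), "ABCD")
        for (i, a), (j, b) in itertools.combinations(enumerate("ABCD"), 2):
            assert paths[(a, b)] == pytest.approx(d[i, j], abs=1e-9)

    def test_random_additive_matrix_reproduced(self):
        # distances generated from a random tree are additive by construction
        rng = np.random.default_rng(3)
        taxa = [f"t{i}" for i in range(7)]
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=len(taxa),
            rng=__import__("random").Random(42))
        for i, leaf in enumerate(tree.leaf_node_iter()):
            leaf.taxon.label = taxa[i]
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = float(rng.uniform(0.1, 1.0))
        pdm = tree.phylogenetic_distance_matrix()
        tmap = {t.label: t for t in tree.taxon_namespace}
        d = np.zeros((len(taxa), len(taxa)))
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i != j:
                    d[i, j] = pdm.distance(tmap[a], tmap[b])
        paths = _path_lengths(nj_tree(DistanceMatrix(taxa, d)), taxa)
        for (i, a), (j, b) in itertools.combinations(enumerate(taxa), 2):
            assert paths[(a, b)] == pytest.approx(d[i, j], abs=1e-9)

    def test_three_taxa_linear_solve(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 3, 5], [3, 0, 4], [5, 4, 0.0]]))
        paths = _path_lengths(nj_tree(dm), "ABC")
        assert paths[("A", "B")] == pytest.approx(3, abs=1e-9)
        assert paths[("A", "C")] == pytest.approx(5, abs=1e-9)
        assert paths[("B", "C")] == pytest.approx(4, abs=1e-9)

    def test_star_matrix_zero_internal_branch(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        newick = nj_tree(DistanceMatrix(list("ABCD"), d))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        internal = [e.length for e in tree.preorder_edge_iter()
                    if e.head_node and not e.head_node.is_leaf()
                    and e.length is not None]
        assert all(l == pytest.approx(0.0, abs=1e-9) for l in internal)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2))))


@pytest.fixture(scope="module")
def exemplars():
    return [(family, SeqRecord(f"{family}|exemplar", seq))
            for family, seq in fam.exemplar_sequences()]


class TestAssignFamily:
    def test_exemplar_self_assignment(self, exemplars):
        family, rec = exemplars[0]
        asn = assign_family(rec, exemplars)
        assert asn.family == family
        assert asn.distance == pytest.approx(0.0, abs=1e-12)

    def test_truth_round_trip_all_families(self, exemplars):
        for family in fam.ALL_FAMILIES:
            for copy in (0, 1, 2):
                if family.startswith("avenin"):
                    seq = fam.avenin_cds(family, copy)
                elif family.startswith("globulin"):
                    seq = fam.globulin_genomic_cds(family, copy)[0]
                else:
                    seq = fam.aati_cds(family, copy)
                asn = assign_family(SeqRecord("g", seq), exemplars)
                assert asn.family == family, (family, copy, asn)
                assert asn.margin > 0

    def test_random_sequence_unclassified(self, exemplars):
        rng = np.random.default_rng(13)
        rand = "".join(rng.choice(list("ACGT"), size=700))
        asn = assign_family(SeqRecord("r", rand), exemplars, max_dist=1.0)
        assert asn.family == "unclassified"

    def test_empty_exemplars_error(self):
        with pytest.raises(ValueError):
            assign_family(SeqRecord("g", "ACGT"), [])
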