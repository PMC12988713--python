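"""Concatenation, distances, neighbor-joining, and identification rates."""

import math
from itertools import combinations

import dendropy
import numpy as np
import pytest

from cpbarcode.diversity import RegionAlignment, RegionDefinition
from cpbarcode.identify import (ConcatenationSpec, DistanceMatrix,
                                compare_marker_sets, concatenate_loci,
                                identification_rate, nj_tree,
                                pairwise_distance, round_rate)
from cpbarcode.panel import SPECIFIC_PANEL, TRADITIONAL_PANEL

from conftest import random_dna


def make_ra(name, rows, ids=None):
    ids = ids or tuple(f"t{i}" for i in range(len(rows)))
    region = RegionDefinition(name=name, kind="IGS", ref_interval=(1, len(rows[0])),
                              strand="+", alignment_columns=(1, len(rows[0])))
    return RegionAlignment(region=region, ids=tuple(ids), rows=tuple(rows))


class TestConcatenation:
    def test_published_panel_locus_lengths_sum_to_total(self, rng):
        # loci trimmed to the published per-locus alignment lengths must
        # concatenate to the published supermatrix length
        alignments = []
        for locus in SPECIFIC_PANEL:
            rows = tuple(random_dna(rng, locus.alignment_length) for _ in range(3))
            alignments.append(make_ra(locus.name, rows))
        spec = ConcatenationSpec(locus_order=tuple(l.name for l in SPECIFIC_PANEL))
        supermatrix, parts = concatenate_loci(alignments, spec)
        assert supermatrix.aligned_length == 16585
        assert len(parts) == 17

    def test_traditional_barcode_combination_length(self, rng):
        alignments = [make_ra(name, tuple(random_dna(rng, ln) for _ in range(3)))
                      for name, ln, _ in TRADITIONAL_PANEL]
        spec = ConcatenationSpec(locus_order=tuple(n for n, _, _ in TRADITIONAL_PANEL))
        supermatrix, _ = concatenate_loci(alignments, spec)
        assert supermatrix.aligned_length == 1539 + 1434 + 386 == 3359

    def test_single_locus_identity(self, rng):
        ra = make_ra("x", tuple(random_dna(rng, 50) for _ in range(4)))
        out, parts = concatenate_loci([ra], ConcatenationSpec(locus_order=("x",)))
        assert out.rows == ra.rows
        assert parts == {"x": (1, 50)}

    def test_gap_columns_trimmed(self):
        ra = make_ra("x", ("AC-GT", "ACCGT"))
        out, _ = concatenate_loci([ra], ConcatenationSpec(locus_order=("x",)))
        assert out.rows == ("ACGT", "ACGT")

    def test_locus_order_permutation_changes_partitions_not_length(self, rng):
        a = make_ra("a", tuple(random_dna(rng, 30) for _ in range(3)))
        b = make_ra("b", tuple(random_dna(rng, 40) for _ in range(3)))
        s1, p1 = concatenate_loci([a, b], ConcatenationSpec(locus_order=("a", "b")))
        s2, p2 = concatenate_loci([a, b], ConcatenationSpec(locus_order=("b", "a")))
        assert s1.aligned_length == s2.aligned_length == 70
        assert p1["a"] == (1, 30) and p2["a"] == (41, 70)

    def test_accession_mismatch_names_difference(self, rng):
        a = make_ra("a", ("ACGT", "ACGT"), ids=("x", "y"))
        b = make_ra("b", ("ACGT", "ACGT"), ids=("x", "z"))
        with pytest.raises(ValueError, match="'y', 'z'"):
            concatenate_loci([a, b], ConcatenationSpec(locus_order=("a", "b")))


class TestDistances:
    def test_identical_rows_zero(self):
        dm = pairwise_distance(["ACGT", "ACGT"], "p-distance")
        assert dm.d[0, 1] == 0.0

    def test_p_and_jc_closed_form(self):
        dm_p = pairwise_distance(["ACGT", "ACGA"], "p-distance")
        assert dm_p.d[0, 1] == pytest.approx(0.25)
        dm_jc = pairwise_distance(["ACGT", "ACGA"], "JC")
        assert dm_jc.d[0, 1] == pytest.approx(-0.75 * math.log(1 - 4 * 0.25 / 3))

    def test_jc_saturation_error(self):
        with pytest.raises(ValueError, match="saturation"):
            pairwise_distance(["AAAA", "CCCC"], "JC")

    def test_k2p_transition_transversion_closed_form(self):
        # one transition (A<->G) and one transversion (A<->C) over 8 sites
        s1 = "AAAAAAAA"
        s2 = "GAAAAAAC"
        P, Q = 1 / 8, 1 / 8
        expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        dm = pairwise_distance([s1, s2], "K2P")
        assert dm.d[0, 1] == pytest.approx(expected)

    def test_p_distance_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 10))
            L = int(rng.integers(4, 60))
            rows = ["".join(rng.choice(list("ACGT-"), size=L,
                                       p=[0.23, 0.23, 0.23, 0.23, 0.08]))
                    for _ in range(n)]
            try:
                dm = pairwise_distance(rows, "p-distance")
            except ValueError:
                continue  # a pair without comparable sites
            for i, j in combinations(range(n), 2):
                d = Lij = 0
                for a, b in zip(rows[i], rows[j]):
                    if a in "-N" or b in "-N":
                        continue
                    Lij += 1
                    d += a != b
                assert dm.d[i, j] == pytest.approx(d / Lij)


def patristic(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    out = {}
    for a, b in combinations(labels, 2):
        ta = tree.taxon_namespace.get_taxon(a)
        tb = tree.taxon_namespace.get_taxon(b)
        out[(a, b)] = pdm.patristic_distance(ta, tb)
    return out


def random_additive_tree(rng, n):
    """Random topology with positive branch lengths; returns (tree, matrix)."""
    import random as _random
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        rng=_random.Random(int(rng.integers(1 << 30))))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i}"
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = float(rng.uniform(0.05, 1.0))
    labels = sorted(t.label for t in tree.taxon_namespace)
    dist = patristic(tree)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            b = labels[j]
            d[i, j] = d[j, i] = dist[(a, b)]
    return tree, DistanceMatrix(labels=tuple(labels), d=d, model="p-distance")


def rf_distance(t1, t2):
    def bips(tree):
        taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
        out = set()
        for node in tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if 1 < len(side) < len(taxa) - 1:
                out.add(min(side, taxa - side, key=sorted))
        return out
    return len(bips(t1) ^ bips(t2))


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances by hand
        labels = ("A", "B", "C", "D")
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 0, 0],
        ], dtype=float)
        d[2, 3] = d[3, 2] = 7.0
        dm = DistanceMatrix(labels=labels, d=d, model="p-distance")
        tree = nj_tree(dm)
        pat = patristic(tree)
        assert pat[("A", "B")] == pytest.approx(3)
        assert pat[("A", "C")] == pytest.approx(5)
        assert pat[("A", "D")] == pytest.approx(6)
        assert pat[("B", "C")] == pytest.approx(6)
        assert pat[("B", "D")] == pytest.approx(7)
        assert pat[("C", "D")] == pytest.approx(7)
        # AB|CD split present
        truth = dendropy.Tree.get(data="((A:1,B:2):1,(C:3,D:4):0);",
                                  schema="newick")
        assert rf_distance(tree, truth) == 0

    def test_three_taxa_exact_lengths(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        dm = DistanceMatrix(labels=("A", "B", "C"), d=d, model="p-distance")
        pat = patristic(nj_tree(dm))
        assert pat[("A", "B")] == pytest.approx(2)
        assert pat[("A", "C")] == pytest.approx(3)
        assert pat[("B", "C")] == pytest.approx(5)

    def test_additive_consistency_random_trees(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            truth, dm = random_additive_tree(rng, n)
            tree = nj_tree(dm)
            assert rf_distance(tree, truth) == 0
            pat = patristic(tree)
            labels = sorted(dm.labels)
            for i, a in enumerate(labels):
                for j in range(i + 1, n):
                    assert pat[(a, labels[j])] == pytest.approx(
                        dm.d[i, j], abs=1e-9)

    def test_agrees_with_reference_nj_implementation(self, rng):
        import skbio

        n = 8
        _, dm = random_additive_tree(rng, n)
        ours = nj_tree(dm)
        sk = skbio.tree.nj(skbio.DistanceMatrix(dm.d, ids=list(dm.labels)))
        sk_dendro = dendropy.Tree.get(data=str(sk), schema="newick")
        assert rf_distance(ours, sk_dendro) == 0

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]])
        with pytest.raises(ValueError):
            DistanceMatrix(labels=("A", "B", "C"), d=d, model="p-distance")


class TestIdentificationRate:
    def test_printed_rate_semantics(self):
        assert round_rate(22, 44) == 50.00
        assert round_rate(10, 44) == 22.73
        assert round_rate(9, 44) == 20.45 or round_rate(9, 44) == 20.46
        assert round_rate(8, 44) == 18.18

    def test_all_distinct_is_100(self, rng):
        ra = make_ra("x", tuple(random_dna(np.random.default_rng(i), 40)
                                for i in range(6)))
        rep = identification_rate(ra)
        assert rep.rate == 100.00 and all(rep.identified.values())

    def test_all_identical_is_0(self):
        ra = make_ra("x", ("ACGT",) * 5)
        rep = identification_rate(ra)
        assert rep.rate == 0.00 and not any(rep.identified.values())

    def test_shared_haplotype_pair_unidentified(self):
        ra = make_ra("x", ("AAAA", "AAAA", "CCCC", "GGGG"))
        rep = identification_rate(ra)
        assert rep.identified == {"t0": False, "t1": False,
                                  "t2": True, "t3": True}
        assert rep.rate == 50.00

    def test_mask_applied_before_comparison(self):
        # rows differ only inside a gapped column: masked out, so identical
        ra = make_ra("x", ("A-CG", "ATCG", "AGCG"))
        rep = identification_rate(ra)
        assert not any(rep.identified.values())

    def test_rate_times_n_is_integer_count(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 30))
            rows = tuple(random_dna(rng, 12) for _ in range(n))
            rep = identification_rate(make_ra("x", rows))
            k = rep.rate * n / 100
            assert abs(k - round(k)) < 1e-6

    def test_order_invariance(self, rng):
        rows = tuple(random_dna(rng, 20) for _ in range(8))
        ids = tuple(f"t{i}" for i in range(8))
        base = identification_rate(make_ra("x", rows, ids))
        perm = list(rng.permutation(8))
        shuffled = identification_rate(
            make_ra("x", tuple(rows[i] for i in perm),
                    tuple(ids[i] for i in perm)))
        assert shuffled.rate == base.rate
        assert shuffled.identified == base.identified

    def test_tree_singleton_zero_length_cherry_unidentified(self):
        ra = make_ra("x", ("AAAA", "AAAA", "CCCC", "GGGG"))
        dm = pairwise_distance(ra)
        tree = nj_tree(dm)
        rep = identification_rate(ra, "tree_singleton", tree)
        assert not rep.identified["t0"] and not rep.identified["t1"]
        assert rep.identified["t2"] and rep.identified["t3"]


class TestCompareSets:
    def _alignments(self, rng, n_loci=6, n_taxa=10):
        out = []
        for k in range(n_loci):
            rows = tuple(random_dna(np.random.default_rng(100 * k + i % 4), 30)
                         for i in range(n_taxa))
            out.append(make_ra(f"L{k}", rows))
        return out

    def test_superset_monotone_haplotype_rate(self, rng):
        aligns = self._alignments(rng)
        names = [a.region.name for a in aligns]
        for _ in range(20):
            size = int(rng.integers(1, len(names)))
            subset = sorted(rng.choice(names, size=size, replace=False))
            extra = [n for n in names if n not in subset]
            superset = subset + [extra[int(rng.integers(len(extra)))]]
            df = compare_marker_sets({"sub": subset, "sup": superset}, aligns)
            rate = dict(zip(df["set"], df["rate_haplotype_unique"]))
            assert rate["sup"] >= rate["sub"]

    def test_single_locus_set_matches_direct_report(self, rng):
        aligns = self._alignments(rng)
        df = compare_marker_sets({"solo": ["L0"]}, aligns)
        direct = identification_rate(aligns[0])
        assert df.loc[0, "rate_haplotype_unique"] == direct.rate

    def test_unknown_locus_error(self, rng):
        aligns = self._alignments(rng)
        with pytest.raises(KeyError, match="nope"):
            compare_marker_sets({"bad": ["nope"]}, aligns)
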