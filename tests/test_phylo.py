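"""Distances, neighbor joining, bootstrap, cross-species search, rank correlation."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from ribodiv import (
    bipartitions,
    bootstrap_support,
    cross_species_search,
    locus_diversity_summary,
    neighbor_joining,
    pairwise_distance,
)
from ribodiv.cluster import cluster_by_profile
from ribodiv.profiles import SUB, Variant, VariantProfile

from .oracles import AdditiveTree


def clade_sequences():
    """Five sequences with two clean clades (t1,t2) and (t3,t4)."""
    base = "A" * 60

    def mut(s, positions, b):
        s = list(s)
        for p in positions:
            s[p] = b
        return "".join(s)

    shared12 = mut(base, range(0, 10), "C")
    shared34 = mut(base, range(20, 30), "T")
    return [
        ("t1", shared12),
        ("t2", shared12[:55] + "GGGGG"),
        ("t3", shared34),
        ("t4", shared34[:50] + "C" * 10),
        ("t5", base),
    ]


class TestPairwiseDistance:
    def test_identical_sequences_have_zero_distance(self):
        dm = pairwise_distance([("a", "ACGTACGT"), ("b", "ACGTACGT")])
        assert dm["a", "b"] == 0.0

    def test_p_distance_three_mismatches_over_240(self, template, panel3):
        from ribodiv.cluster import consensus_sequence

        a, b = template.span_ITS1
        ref_its1 = template.region_sequence("ITS1")
        var_its1 = consensus_sequence(template, panel3.profiles[2])[a - 1 : b]
        dm = pairwise_distance([("ref", ref_its1), ("var", var_its1)])
        assert dm["ref", "var"] == pytest.approx(3 / 240)

    def test_jukes_cantor_closed_form(self):
        seqs = [("a", "A" * 237 + "CCC"), ("b", "A" * 237 + "GGG")]
        dm = pairwise_distance(seqs, model="jc")
        p = 3 / 240
        assert dm["a", "b"] == pytest.approx(-0.75 * math.log1p(-4 * p / 3))
        assert dm["a", "b"] == pytest.approx(0.012605, abs=1e-6)

    def test_gapped_columns_excluded_pairwise(self):
        dm = pairwise_distance([("a", "AC-T"), ("b", "ACGT")])
        assert dm["a", "b"] == 0.0

    def test_saturated_jc_flagged_undefined(self):
        dm = pairwise_distance([("a", "AAAA"), ("b", "CCCC")], model="jc")
        assert math.isinf(dm["a", "b"])


class TestNeighborJoining:
    def test_three_taxon_closed_form_branch_lengths(self):
        dm = DistanceMatrix(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float),
                            ["a", "b", "c"])
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        # v_a = (d_ab + d_ac - d_bc)/2 etc.
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(np.array([[0, 1], [1, 0]], float), ["a", "b"])
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_recovers_additive_topologies(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            true = AdditiveTree(int(rng.integers(5, 9)), rng)
            labels, mat = true.distances()
            tree = neighbor_joining(DistanceMatrix(mat, labels))
            assert bipartitions(tree) == true.bipartitions()

    def test_no_negative_branch_lengths_after_clamping(self):
        # random noisy (non-additive) matrices routinely induce negative NJ
        # branch estimates; clamping must leave every length non-negative
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 8))
            noise = rng.uniform(0.1, 1.0, size=(n, n))
            mat = (noise + noise.T) / 2
            np.fill_diagonal(mat, 0.0)
            labels = [f"x{i}" for i in range(n)]
            tree = neighbor_joining(DistanceMatrix(mat, labels))
            assert all(
                n_.length >= 0 for n_ in tree.traverse() if n_.length is not None
            )

    def test_negative_length_deficit_moves_to_sister_edge(self):
        from skbio.tree import TreeNode

        from ribodiv.phylo import _transfer_negative_lengths

        tree = TreeNode.read(["((a:-0.4,b:1.0):0.5,c:0.2,d:0.3);"])
        out = _transfer_negative_lengths(tree)
        lengths = {t.name: t.length for t in out.tips()}
        assert lengths["a"] == 0.0
        assert lengths["b"] == pytest.approx(0.6)  # sister absorbs the deficit

    def test_two_ribotype_groups_bipartitioned_by_one_edge(self):
        # two families separated by a large distance form a clean split
        seqs = clade_sequences()[:4]
        tree = neighbor_joining(pairwise_distance(seqs))
        parts = bipartitions(tree)
        expected = frozenset({frozenset({"t1", "t2"}), frozenset({"t3", "t4"})})
        assert expected in parts


class TestBootstrap:
    def test_clean_clades_get_full_support(self):
        tree, support = bootstrap_support(clade_sequences(), n_replicates=100, seed=5)
        assert len(support) == 2
        assert all(s >= 90 for s in support.values())

    def test_single_replicate_supports_are_zero_or_hundred(self):
        _, support = bootstrap_support(clade_sequences(), n_replicates=1, seed=3)
        assert set(support.values()) <= {0.0, 100.0}

    def test_identical_sequences_support_nothing(self):
        seqs = [(f"t{i}", "ACGT" * 10) for i in range(4)]
        _, support = bootstrap_support(seqs, n_replicates=20, seed=1)
        assert all(s == 0.0 for s in support.values())

    def test_support_invariant_to_input_order(self):
        seqs = clade_sequences()
        _, s1 = bootstrap_support(seqs, n_replicates=50, seed=9)
        _, s2 = bootstrap_support(list(reversed(seqs)), n_replicates=50, seed=9)
        assert s1 == s2


class TestCrossSpeciesSearch:
    @staticmethod
    def tables(template):
        p_a = VariantProfile([Variant(320, SUB, ref=template.sequence[319],
                                      alt="A" if template.sequence[319] != "A" else "G")])
        p_b = VariantProfile([Variant(400, SUB, ref=template.sequence[399],
                                      alt="C" if template.sequence[399] != "C" else "T")])
        reads_a = [(f"a{i}", p_a) for i in range(20)] + [(f"a{i+20}", VariantProfile()) for i in range(80)]
        reads_b = [(f"b{i}", p_b) for i in range(3)]
        table_a = cluster_by_profile(reads_a, "ITS1", species="A")
        table_b = cluster_by_profile(reads_b, "ITS1", species="B")
        return p_a, p_b, table_a, table_b

    def test_verbatim_low_copy_cluster_is_found(self, template):
        from ribodiv.cluster import consensus_sequence

        p_a, p_b, table_a, table_b = self.tables(template)
        query = [("B_RT0", consensus_sequence(template, p_b))]
        matches = cross_species_search(query, [(table_b, template)])
        assert len(matches["B_RT0"]) == 1
        assert matches["B_RT0"][0].target_count == 3  # low-copy still reported

    def test_disjoint_panels_share_no_ribotypes(self, template):
        from ribodiv.cluster import consensus_sequence

        p_a, p_b, table_a, table_b = self.tables(template)
        queries = [("A_RT0", consensus_sequence(template, p_a))]
        matches = cross_species_search(queries, [(table_b, template)])
        assert matches["A_RT0"] == []

    def test_max_mismatch_at_length_matches_everything(self, template):
        from ribodiv.cluster import consensus_sequence

        p_a, p_b, table_a, table_b = self.tables(template)
        queries = [("A_RT0", consensus_sequence(template, p_a))]
        matches = cross_species_search(
            queries, [(table_b, template)], max_mismatch=len(template)
        )
        assert len(matches["A_RT0"]) == len(table_b.clusters)


class TestLocusDiversitySummary:
    def test_rho_matches_midrank_formula(self):
        records = [("sp1", 1, 1), ("sp2", 3, 2), ("sp3", 2, 2), ("sp4", 4, 3)]
        _, rho = locus_diversity_summary(records)
        # midrank oracle: loci ranks (1,3,2,4); ribotype ranks (1,2.5,2.5,4)
        rx = np.array([1.0, 3.0, 2.0, 4.0])
        ry = np.array([1.0, 2.5, 2.5, 4.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected)

    def test_concordant_and_reversed_ranks(self):
        inc = [("a", 1, 1), ("b", 2, 2), ("c", 3, 3)]
        dec = [("a", 1, 3), ("b", 2, 2), ("c", 3, 1)]
        assert locus_diversity_summary(inc)[1] == pytest.approx(1.0)
        assert locus_diversity_summary(dec)[1] == pytest.approx(-1.0)

    def test_fewer_than_three_records_rejected(self):
        with pytest.raises(ValueError):
            locus_diversity_summary([("a", 1, 1), ("b", 2, 2)])


def test_consensus_distance_equals_profile_distance(template, panel3):
    """Distance via consensus sequences == distance counted from profiles."""
    from ribodiv.cluster import consensus_sequence

    seqs = [(f"RT{i}", consensus_sequence(template, p)) for i, p in enumerate(panel3.profiles)]
    dm = pairwise_distance(seqs)
    for i, pi in enumerate(panel3.profiles):
        for j, pj in enumerate(panel3.profiles):
            if i < j:
                positions_i = {(v.position, v.alt) for v in pi}
                positions_j = {(v.position, v.alt) for v in pj}
                diff = len(positions_i ^ positions_j)
                assert dm[f"RT{i}", f"RT{j}"] == pytest.approx(diff / len(template))
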