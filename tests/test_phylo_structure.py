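"""Distances, neighbor joining, bootstrap supports, Evanno delta-K."""

import math
import random

import numpy as np
import pandas as pd
import pytest

import helpers_oracle as oracle
from conftest import make_matrix
from dsrscan.diffstat import Contrast, fst_scan, multilocus_theta
from dsrscan.phylo_structure import (
    DistanceMatrix,
    PhyloTree,
    allele_sharing_distance,
    bootstrap_support,
    evanno_delta_k,
    neighbor_joining,
)
from dsrscan.synthetic_data import SimConfig, simulate


class TestDistances:
    def test_identical_individuals_distance_zero(self):
        m = make_matrix([[0, 1, 2, 1], [0, 1, 2, 1]], ["A", "B"])
        dm = allele_sharing_distance(m)
        assert dm.d[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        m = make_matrix([[0, 0, 0], [2, 2, 2]], ["A", "B"])
        assert allele_sharing_distance(m).d[0, 1] == 1.0

    def test_half_identical_half_opposite(self):
        m = make_matrix([[0, 0, 0, 0], [0, 0, 2, 2]], ["A", "B"])
        assert allele_sharing_distance(m).d[0, 1] == pytest.approx(0.5)

    def test_missing_loci_excluded_pairwise(self):
        m = make_matrix([[0, -1, 0], [0, 2, 2]], ["A", "B"])
        # only loci 0 and 2 co-called: identical + opposite -> 0.5
        assert allele_sharing_distance(m).d[0, 1] == pytest.approx(0.5)

    def test_no_shared_loci_is_error(self):
        m = make_matrix([[0, -1], [-1, 2]], ["A", "B"])
        with pytest.raises(ValueError, match="no called loci"):
            allele_sharing_distance(m)

    def test_breed_level_equals_pairwise_multilocus_theta(self, rng):
        g = rng.integers(0, 3, size=(12, 300)).astype(np.int8)
        m = make_matrix(g, ["A"] * 4 + ["B"] * 4 + ["C"] * 4)
        dm = allele_sharing_distance(m, level="breed")
        expect = multilocus_theta(fst_scan(m, Contrast("x", {"A"}, {"B"})))
        assert dm.d[0, 1] == pytest.approx(max(expect, 0.0))
        assert dm.labels == ["A", "B", "C"]


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array(
            [[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]
        ))
        tree = neighbor_joining(dm)
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 1.5], [1.5, 0.0]]))
        tree = neighbor_joining(dm)
        assert tree.patristic_distances().d[0, 1] == pytest.approx(1.5)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(labels, d))
        bips = tree.bipartitions()
        assert len(bips) == 1
        (split, node), = bips.items()
        assert split in (frozenset({"A", "B"}), frozenset({"C", "D"}))
        assert node.length == pytest.approx(1.0)
        induced = tree.patristic_distances()
        np.testing.assert_allclose(induced.d, d, atol=1e-12)

    def test_random_additive_trees_round_trip(self):
        rng = random.Random(2024)
        for _ in range(25):
            n = rng.randint(4, 8)
            labels, mat = oracle.random_additive_tree(rng, n)
            tree = neighbor_joining(DistanceMatrix(labels, np.array(mat)))
            induced = tree.patristic_distances()
            # induced labels are sorted; reorder the input to match
            order = [labels.index(lab) for lab in induced.labels]
            expect = np.array(mat)[np.ix_(order, order)]
            np.testing.assert_allclose(induced.d, expect, atol=1e-9)

    def test_tie_break_deterministic(self):
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(["A", "B", "C", "D"], d)
        assert neighbor_joining(dm).to_newick() == neighbor_joining(dm).to_newick()

    def test_agrees_with_independent_nj_implementation(self, rng):
        # generic (tie-free) random matrix: topology should match scikit-bio
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        n = 7
        base = rng.uniform(1.0, 2.0, size=(n, n))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [f"T{i}" for i in range(n)]
        mine = neighbor_joining(DistanceMatrix(labels, d))
        ref = skbio_nj(SkbioDM(d, ids=labels))
        ref_tree = PhyloTree.from_newick(str(ref).strip())
        assert set(mine.bipartitions()) == set(ref_tree.bipartitions())


class TestNewick:
    def test_round_trip_stable(self):
        dm = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array(
                [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
            ),
        )
        tree = neighbor_joining(dm)
        first = tree.to_newick()
        second = PhyloTree.from_newick(first).to_newick()
        assert first == second

    def test_leaf_set_preserved(self):
        t = PhyloTree.from_newick("((A:1,B:2):0.5,(C:3,D:4):0.5,E:1);")
        assert sorted(t.labels) == ["A", "B", "C", "D", "E"]


class TestBootstrap:
    def test_constant_loci_give_full_support(self):
        # every locus identical: all replicate trees equal the point tree
        col = np.array([0, 0, 1, 1, 2, 2, 2, 0])
        g = np.tile(col[:, None], (1, 40)).astype(np.int8)
        m = make_matrix(g, ["A"] * 4 + ["B"] * 4)
        tree = bootstrap_support(m, n_reps=25, seed=3)
        supports = [n.support for n in tree.bipartitions().values()]
        assert supports and all(s == 100.0 for s in supports)

    def test_deterministic_for_fixed_seed(self, rng):
        g = rng.integers(0, 3, size=(10, 120)).astype(np.int8)
        m = make_matrix(g, ["A"] * 5 + ["B"] * 5)
        t1 = bootstrap_support(m, n_reps=20, seed=11)
        t2 = bootstrap_support(m, n_reps=20, seed=11)
        assert t1.to_newick() == t2.to_newick()

    def test_supports_invariant_to_sample_order_permutation(self, rng):
        cfg = SimConfig(
            breeds=[("A", 4), ("B", 4)], n_chrom=1, snps_per_chrom=300,
            background_F=0.3, missing_rate=0.0, seed=9,
        )
        m, _ = simulate(cfg)
        perm = rng.permutation(m.n_samples)
        m_perm = m.take_samples(perm)
        t1 = bootstrap_support(m, n_reps=30, seed=5)
        t2 = bootstrap_support(m_perm, n_reps=30, seed=5)
        s1 = {k: n.support for k, n in t1.bipartitions().items()}
        s2 = {k: n.support for k, n in t2.bipartitions().items()}
        # breed bipartitions exist in both and carry equal support
        key = frozenset(s for s in m.sample_ids if m.breed_of[s] == "A")
        ref1 = t1.labels[0]
        all1 = frozenset(t1.labels)
        key1 = key if ref1 not in key else all1 - key
        assert key1 in s1 and key1 in s2
        assert s1[key1] == pytest.approx(s2[key1], abs=1e-9)


class TestEvanno:
    @staticmethod
    def replicate_table(means, sd=1.0, k0=1):
        """Two replicates offset +/- sd/sqrt(2): replicate sd is exactly
        ``sd`` and second differences are unchanged."""
        delta = sd / math.sqrt(2)
        rows = []
        for i, mu in enumerate(means):
            rows.append((k0 + i, 1, mu - delta))
            rows.append((k0 + i, 2, mu + delta))
        return pd.DataFrame(rows, columns=["K", "replicate", "lnP"])

    def test_worked_example_optimal_k_three(self):
        table = self.replicate_table([-100.0, -80.0, -50.0, -48.0, -47.0])
        res = evanno_delta_k(table)
        interior = res.table.dropna(subset=["delta_k"])
        assert interior["mean_abs_lppK"].tolist() == pytest.approx([10.0, 28.0, 1.0])
        assert interior["sd_lnP"].tolist() == pytest.approx([1.0, 1.0, 1.0])
        assert res.optimal_k == 3
        assert not res.tied

    def test_fewer_than_three_k_is_error(self):
        with pytest.raises(ValueError, match="3 distinct K"):
            evanno_delta_k(self.replicate_table([-10.0, -9.0]))

    def test_zero_variance_is_error(self):
        rows = [(k, r, -10.0 * k) for k in (1, 2, 3) for r in (1, 2)]
        table = pd.DataFrame(rows, columns=["K", "replicate", "lnP"])
        with pytest.raises(ValueError, match="zero variance"):
            evanno_delta_k(table)

    def test_linear_profile_reported_as_tie(self, caplog):
        import logging

        table = self.replicate_table([-100.0, -90.0, -80.0, -70.0])
        with caplog.at_level(logging.WARNING):
            res = evanno_delta_k(table)
        assert res.tied
        assert "tied" in caplog.text

    def test_single_replicate_rejected(self):
        table = pd.DataFrame(
            [(1, 1, -5.0), (2, 1, -4.0), (3, 1, -3.0)],
            columns=["K", "replicate", "lnP"],
        )
        with pytest.raises(ValueError, match="replicates"):
            evanno_delta_k(table)
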