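"""UPGMA trees, Newick round-trips, patristic sums and representatives."""

import math

import dendropy
import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from trxmine.errors import DataError, ParseError
from trxmine.family_mining import SequenceRecord
from trxmine.phylo_rep import (
    DistanceMatrix,
    pairwise_distances,
    patristic_matrix,
    patristic_sums,
    read_newick,
    select_additional_representatives,
    select_medoid,
    upgma,
    write_newick,
)
from trxmine.simulate import yule_tree


def random_matrix(rng, n):
    d = rng.uniform(0.1, 2.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return DistanceMatrix(labels=[f"t{i}" for i in range(n)], d=d)


class TestPairwiseDistances:
    def test_identical_is_zero(self):
        recs = [SequenceRecord(id="A", residues="MCGPC"),
                SequenceRecord(id="B", residues="MCGPC")]
        m = pairwise_distances(recs)
        assert m.d[0, 1] == 0

    def test_one_mismatch_in_four(self):
        recs = [SequenceRecord(id="A", residues="AAAA"),
                SequenceRecord(id="B", residues="AAAT")]
        assert pairwise_distances(recs).d[0, 1] == pytest.approx(0.25)

    def test_single_record_rejected(self):
        with pytest.raises(DataError):
            pairwise_distances([SequenceRecord(id="A", residues="MA")])

    def test_symmetry(self, sim_dataset):
        recs = sim_dataset.records[:6]
        m = pairwise_distances(recs)
        assert np.allclose(m.d, m.d.T)


class TestUpgma:
    def test_two_leaves(self):
        m = DistanceMatrix(labels=["A", "B"], d=np.array([[0.0, 2.0], [2.0, 0.0]]))
        tree = upgma(m)
        (a, b) = tree.root.children
        assert a.branch_length == b.branch_length == 1.0

    def test_three_leaf_hand_execution(self):
        m = DistanceMatrix(labels=["A", "B", "C"],
                           d=np.array([[0.0, 2.0, 8.0],
                                       [2.0, 0.0, 8.0],
                                       [8.0, 8.0, 0.0]]))
        tree = upgma(m)
        ab, c = tree.root.children
        assert c.label == "C" and c.branch_length == pytest.approx(4.0)
        assert ab.branch_length == pytest.approx(3.0)
        assert all(child.branch_length == pytest.approx(1.0)
                   for child in ab.children)

    def test_ultrametric_output(self, rng):
        for _ in range(20):
            tree = upgma(random_matrix(rng, int(rng.integers(3, 12))))
            depths = list(tree.leaf_depths().values())
            assert max(depths) - min(depths) < 1e-9

    def test_recovers_ultrametric_input_exactly(self, rng):
        for _ in range(10):
            source = yule_tree(8, rng)
            m = patristic_matrix(source)
            tree = upgma(m)
            back = patristic_matrix(tree)
            assert back.labels == m.labels
            assert np.allclose(back.d, m.d, atol=1e-9)

    def test_matches_scipy_average_linkage(self, rng):
        """Cophenetic distances from our UPGMA equal scipy's average-linkage
        cophenetic matrix (independent implementation of the same method)."""
        for _ in range(10):
            m = random_matrix(rng, 7)
            link = hierarchy.linkage(squareform(m.d), method="average")
            coph = squareform(hierarchy.cophenet(link))
            ours = patristic_matrix(upgma(m))
            order = [ours.labels.index(lbl) for lbl in m.labels]
            assert np.allclose(ours.d[np.ix_(order, order)], coph, atol=1e-9)

    def test_nan_rejected(self):
        with pytest.raises(DataError):
            DistanceMatrix(labels=["A", "B"],
                           d=np.array([[0, np.nan], [np.nan, 0]]))


class TestNewick:
    def test_two_leaf_parse(self):
        tree = read_newick("(A:1,B:1):0;")
        labels = tree.leaf_labels()
        assert labels == ["A", "B"]
        assert all(leaf.branch_length == 1.0 for leaf in tree.leaves())

    def test_round_trip_of_upgma_output(self, rng):
        tree = upgma(random_matrix(rng, 9))
        text = write_newick(tree)
        assert write_newick(read_newick(text)) == text

    def test_patristic_from_parsed_tree(self):
        tree = read_newick("((A:1,B:2):0.5,C:4);")
        m = patristic_matrix(tree)
        d_ac = m.d[m.labels.index("A"), m.labels.index("C")]
        assert d_ac == pytest.approx(5.5)

    @pytest.mark.parametrize("bad", ["(A:1,B:1):0", "((A:1,B:1:0;", "(A:1,B:1)):0;"])
    def test_malformed_input_rejected(self, bad):
        with pytest.raises(ParseError, match="position"):
            read_newick(bad)


class TestPatristicSums:
    def test_two_leaves(self):
        tree = read_newick("(A:1,B:1):0;")
        assert patristic_sums(tree) == {"A": 2.0, "B": 2.0}

    def test_three_leaf_example(self):
        m = DistanceMatrix(labels=["A", "B", "C"],
                           d=np.array([[0.0, 2.0, 8.0],
                                       [2.0, 0.0, 8.0],
                                       [8.0, 8.0, 0.0]]))
        sums = patristic_sums(upgma(m))
        assert sums["A"] == pytest.approx(10.0)
        assert sums["B"] == pytest.approx(10.0)
        assert sums["C"] == pytest.approx(16.0)

    def test_star_tree_closed_form(self):
        n, b = 6, 2.5
        text = "(" + ",".join(f"L{i}:{b}" for i in range(n)) + ");"
        sums = patristic_sums(read_newick(text))
        assert all(s == pytest.approx(2 * b * (n - 1)) for s in sums.values())

    def test_matches_bruteforce_on_random_trees(self, rng):
        """Linear-time sums equal brute-force all-pairs path sums."""
        for _ in range(50):
            tree = yule_tree(int(rng.integers(2, 65)), rng)
            sums = patristic_sums(tree)
            m = patristic_matrix(tree)
            brute = {lbl: m.d[i].sum() for i, lbl in enumerate(m.labels)}
            for lbl in brute:
                assert sums[lbl] == pytest.approx(brute[lbl], abs=1e-9)

    def test_matches_dendropy_oracle(self, rng):
        tree = yule_tree(12, rng)
        text = write_newick(tree)
        dtree = dendropy.Tree.get(data=text, schema="newick")
        pdm = dtree.phylogenetic_distance_matrix()
        oracle = {
            taxon.label: sum(
                pdm.patristic_distance(taxon, other)
                for other in dtree.taxon_namespace if other is not taxon)
            for taxon in dtree.taxon_namespace
        }
        sums = patristic_sums(tree)
        # dendropy reads the 10-significant-digit Newick text, so compare at
        # serialization precision rather than machine precision
        for lbl, val in oracle.items():
            assert sums[lbl] == pytest.approx(val, rel=1e-8, abs=1e-7)


class TestMedoid:
    def test_minimal_sum_wins(self):
        assert select_medoid({"A": 10.0, "B": 10.0, "C": 16.0}) == "A"

    def test_singleton(self):
        assert select_medoid({"X": 5.0}) == "X"

    def test_all_tied_takes_smallest_id(self):
        assert select_medoid({"C": 4.0, "A": 4.0, "B": 4.0}) == "A"


class TestRepresentatives:
    def ladder(self, n, medoid_top=True):
        ids = [f"m{i:04d}" for i in range(1, n + 1)]
        scores = {m: float(i) for i, m in enumerate(ids, 1)}
        medoid = ids[-1] if medoid_top else ids[0]
        return ids, medoid, scores

    def test_small_cluster_single_representative(self):
        ids, medoid, scores = self.ladder(40)
        a = select_additional_representatives(ids, medoid, scores)
        assert a.representatives == [medoid]
        assert all(rep == medoid for rep in a.membership.values())

    def test_150_uniform_ladder_splits_75_75(self):
        ids, medoid, scores = self.ladder(150)
        a = select_additional_representatives(ids, medoid, scores)
        assert len(a.representatives) == 2
        assert sorted(a.loads().values()) == [75, 75]
        assert a.within_bounds

    def test_101_members_two_reps_loads_50_51(self):
        ids, medoid, scores = self.ladder(101)
        a = select_additional_representatives(ids, medoid, scores)
        assert len(a.representatives) == 2
        assert sorted(a.loads().values()) == [50, 51]

    def test_medoid_always_first_and_self_assigned(self):
        ids, medoid, scores = self.ladder(250)
        a = select_additional_representatives(ids, medoid, scores)
        assert a.representatives[0] == medoid
        assert a.membership[medoid] == medoid

    def test_coverage_exactly_once(self):
        ids, medoid, scores = self.ladder(333)
        a = select_additional_representatives(ids, medoid, scores)
        assert set(a.membership) == set(ids)
        assert set(a.membership.values()) <= set(a.representatives)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(DataError):
            select_additional_representatives(
                ["a", "a"], "a", {"a": 1.0})

    @pytest.mark.parametrize("n", [51, 99, 100, 101, 199, 500, 5000, 10000])
    def test_rep_count_keeps_minimum_load(self, n):
        k = math.ceil(n / 100)
        assert n / k >= 50
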