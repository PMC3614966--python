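"""Community comparison metrics and dendrograms."""

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from thaumflow.community import (
    bray_curtis,
    chao_sorensen_abd,
    matrix_correlation_check,
    sample_distance_matrix,
    shared_otu_matrix,
    upgma,
    weighted_unifrac,
)
from thaumflow.errors import MissingTipError, ValidationError

from conftest import branch_by_branch_unifrac, random_symmetric


class TestBrayCurtis:
    def test_identical_zero(self):
        assert bray_curtis([3, 1, 4], [3, 1, 4]) == 0.0

    def test_disjoint_one(self):
        assert bray_curtis([5, 0, 0], [0, 2, 3]) == 1.0

    def test_hand_value(self):
        assert bray_curtis([6, 0, 2], [2, 2, 0]) == pytest.approx(8 / 12)

    def test_both_empty_rejected(self):
        with pytest.raises(ValidationError):
            bray_curtis([0, 0], [0, 0])

    def test_matches_scipy(self, rng):
        from scipy.spatial.distance import braycurtis as scipy_bc

        for _ in range(30):
            x = rng.integers(0, 20, size=8)
            y = rng.integers(0, 20, size=8)
            if x.sum() + y.sum() == 0:
                continue
            assert bray_curtis(x, y) == pytest.approx(scipy_bc(x, y))


class TestChaoSorensen:
    def test_identical_samples_unity(self):
        assert chao_sorensen_abd([5, 3, 2], [5, 3, 2]) == pytest.approx(1.0)

    def test_disjoint_zero(self):
        assert chao_sorensen_abd([5, 0], [0, 7]) == 0.0

    def test_raw_hand_value(self):
        # shared OTU index 0 only: U=0.5, V=0.4 -> 2*0.2/0.9
        assert chao_sorensen_abd([5, 5, 0], [4, 0, 6], corrected=False) == pytest.approx(0.4444, abs=1e-4)

    def test_corrected_at_least_raw(self, rng):
        """The unseen-shared correction only adds mass before clamping."""
        for _ in range(50):
            x = rng.integers(0, 6, size=10)
            y = rng.integers(0, 6, size=10)
            if x.sum() == 0 or y.sum() == 0:
                continue
            assert chao_sorensen_abd(x, y) >= chao_sorensen_abd(x, y, corrected=False) - 1e-12

    def test_symmetric(self, rng):
        for _ in range(20):
            x = rng.integers(0, 9, size=7) + 1
            y = rng.integers(0, 9, size=7) + 1
            assert chao_sorensen_abd(x, y) == pytest.approx(chao_sorensen_abd(y, x))

    def test_shared_otu_matrix_diagonal_and_symmetry(self, rng):
        import pandas as pd

        table = pd.DataFrame(rng.integers(0, 10, size=(4, 6)) + 1,
                             index=list("ABCD"))
        L = shared_otu_matrix(table)
        assert np.allclose(np.diag(L), 1.0)
        assert np.allclose(L, L.T)
        assert ((L >= 0) & (L <= 1)).all().all()


class TestWeightedUnifrac:
    @pytest.fixture
    def balanced_tree(self):
        return TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"])

    def test_identical_samples_zero(self, balanced_tree):
        d = weighted_unifrac(balanced_tree, [1, 2, 3, 0], [1, 2, 3, 0], list("ABCD"))
        assert d == pytest.approx(0.0)

    def test_two_tip_disjoint_normalized_one(self):
        tree = TreeNode.read(["(A:1,B:1);"])
        assert weighted_unifrac(tree, [4, 0], [0, 4], ["A", "B"]) == pytest.approx(1.0)

    def test_balanced_tree_hand_accumulation(self, balanced_tree):
        """x on the left clade, y on the right: every tip branch carries
        |0.5-0| and both internals |1-0|, so raw = 4 and normalized = 1."""
        raw = weighted_unifrac(balanced_tree, [2, 2, 0, 0], [0, 0, 2, 2], list("ABCD"), normalized=False)
        assert raw == pytest.approx(4.0)
        norm = weighted_unifrac(balanced_tree, [2, 2, 0, 0], [0, 0, 2, 2], list("ABCD"))
        assert norm == pytest.approx(1.0)

    def test_missing_tip_listed(self, balanced_tree):
        with pytest.raises(MissingTipError, match="E"):
            weighted_unifrac(balanced_tree, [1, 0, 0, 0, 2], [0, 1, 0, 0, 0], list("ABCDE"))

    def test_matches_independent_per_branch_accumulation(self, rng):
        """Brute-force per-branch oracle on random <=10-tip trees."""
        for k in range(15):
            n = int(rng.integers(3, 11))
            tips = [f"t{i}" for i in range(n)]
            newick = self._random_tree(rng, tips)
            tree = TreeNode.read([newick])
            x = rng.integers(0, 8, size=n)
            y = rng.integers(0, 8, size=n)
            if x.sum() == 0 or y.sum() == 0:
                continue
            for normalized in (False, True):
                mine = weighted_unifrac(tree, x, y, tips, normalized)
                ref = branch_by_branch_unifrac(tree, x, y, tips, normalized)
                assert mine == pytest.approx(ref)

    def test_matches_skbio(self, rng):
        from skbio.diversity.beta import weighted_unifrac as sk_wu

        tips = ["a", "b", "c", "d", "e"]
        tree = TreeNode.read(["(((a:0.3,b:0.2):0.4,c:0.7):0.2,(d:0.5,e:0.1):0.6):0;"])
        for _ in range(10):
            x = rng.integers(0, 9, size=5) + (rng.random(5) < 0.5)
            y = rng.integers(0, 9, size=5)
            if x.sum() == 0 or y.sum() == 0:
                continue
            x = x.astype(int)
            for normalized in (False, True):
                mine = weighted_unifrac(tree, x, y, tips, normalized)
                ref = sk_wu(x, y, taxa=tips, tree=tree, normalized=normalized)
                assert mine == pytest.approx(float(ref))

    @staticmethod
    def _random_tree(rng, tips):
        nodes = [f"{t}:{rng.uniform(0.1, 1):.3f}" for t in tips]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.1, 1):.3f}"
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
        return nodes[0] + ";"


class TestUpgma:
    def test_two_samples_join_at_half_distance(self):
        dm = DistanceMatrix([[0, 0.4], [0.4, 0]], ["A", "B"])
        tree = upgma(dm)
        tips = {t.name: t.length for t in tree.tips()}
        assert tips == {"A": pytest.approx(0.2), "B": pytest.approx(0.2)}

    def test_closest_pair_merges_first(self):
        dm = DistanceMatrix([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]], ["A", "B", "C"])
        tree = upgma(dm)
        # A and B must be siblings
        a = tree.find("A")
        assert {t.name for t in a.parent.tips()} == {"A", "B"}

    def test_ultrametric_tip_depths_equal(self, rng):
        dm = random_symmetric(rng, 8, scale=0.9)
        tree = upgma(dm)
        depths = [t.accumulate_to_ancestor(tree) for t in tree.tips()]
        assert np.allclose(depths, depths[0])

    def test_identical_rows_zero_height_star(self):
        d = np.full((3, 3), 0.3)
        np.fill_diagonal(d, 0)
        tree = upgma(DistanceMatrix(d, ["b", "a", "c"]))
        depths = [t.accumulate_to_ancestor(tree) for t in tree.tips()]
        assert np.allclose(depths, 0.15)

    def test_cophenetic_matches_average_linkage(self, rng):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        dm = random_symmetric(rng, 6, scale=0.8)
        dm = dm.filter(sorted(dm.ids))
        tree = upgma(dm)
        Z = linkage(squareform(dm.data, checks=False), "average")
        expected = squareform(cophenet(Z))
        for i, a in enumerate(dm.ids):
            for j, b in enumerate(dm.ids):
                if i < j:
                    got = tree.find(a).accumulate_to_ancestor(tree) + tree.find(b).accumulate_to_ancestor(tree) - 2 * 0
                    # cophenetic distance = 2 * height of the lowest common ancestor
                    lca = tree.lowest_common_ancestor([a, b])
                    height = tree.find(a).accumulate_to_ancestor(tree) - lca.accumulate_to_ancestor(tree)
                    assert 2 * height == pytest.approx(expected[i, j])


class TestMatrixCorrelation:
    def test_self_correlation_unity(self, rng):
        dm = random_symmetric(rng, 8)
        res = matrix_correlation_check(dm, dm, permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.pvalue == pytest.approx(1 / 100)

    def test_independent_matrices_uncorrelated(self, rng):
        dm1 = random_symmetric(rng, 10)
        dm2 = random_symmetric(rng, 10)
        res = matrix_correlation_check(dm1, dm2, permutations=199, seed=1)
        assert abs(res.statistic) < 0.5

    def test_monotone_transform_near_unity(self, rng):
        dm1 = random_symmetric(rng, 8)
        dm2 = DistanceMatrix(np.sqrt(dm1.data), dm1.ids)
        res = matrix_correlation_check(dm1, dm2, permutations=99, seed=2)
        assert res.statistic > 0.95


class TestSampleDistanceMatrix:
    def test_braycurtis_and_unifrac_matrices_consistent(self, rng):
        import pandas as pd

        tips = list("ABCD")
        tree = TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"])
        table = pd.DataFrame(
            rng.integers(0, 10, size=(3, 4)) + 1, index=["s1", "s2", "s3"], columns=tips
        )
        for metric, kwargs in (("braycurtis", {}), ("unifrac", {"tree": tree})):
            dm = sample_distance_matrix(table, metric=metric, **kwargs)
            assert np.allclose(dm.data, dm.data.T)
            assert np.allclose(np.diag(dm.data), 0)
            assert dm.data.max() <= 1 + 1e-12
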