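import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from metagenehunt.profile import (
    DistanceMatrix,
    bray_curtis,
    complete_linkage,
    distance_matrix,
    shannon,
    structure_function_correlation,
)
from metagenehunt.quantify import CountTable


def table(rows, samples, features=None):
    features = features or [f"f{i}" for i in range(len(rows[0]))]
    return CountTable(
        pd.DataFrame(rows, index=samples, columns=features, dtype=float),
        kind="rarefied",
    )


class TestBrayCurtis:
    def test_identical_vectors_give_zero(self):
        assert bray_curtis([3, 1, 4], [3, 1, 4]) == pytest.approx(0.0)

    def test_disjoint_supports_give_one(self):
        assert bray_curtis([5, 0, 2], [0, 3, 0]) == pytest.approx(1.0)

    def test_hand_value(self):
        assert bray_curtis([6, 2], [2, 2]) == pytest.approx(1 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([1, 2], [1, 2, 3])

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis([0, 0], [0, 0])

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.integers(0, 50, size=(2, 8)).astype(float)
            if x.sum() + y.sum() == 0:
                continue
            assert bray_curtis(x, y) == pytest.approx(scipy_braycurtis(x, y))

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.integers(0, 100), min_size=2, max_size=6),
        st.integers(1, 50),
    )
    def test_invariant_under_joint_rescaling(self, x, c):
        y = x[::-1]
        if sum(x) + sum(y) == 0:
            return
        xa, ya = np.array(x, float), np.array(y, float)
        assert bray_curtis(c * xa, c * ya) == pytest.approx(bray_curtis(xa, ya))


class TestDistanceMatrix:
    def test_identical_rows_give_zero_off_diagonal(self):
        d = distance_matrix(table([[1, 2, 3], [1, 2, 3]], ["a", "b"]))
        assert d[("a", "b")] == pytest.approx(0.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(7)
        rows = rng.integers(0, 100, size=(5, 8)).astype(float)
        samples = list("abcde")
        d = distance_matrix(table(rows, samples))
        for i in range(5):
            for j in range(5):
                expect = 0.0 if i == j else bray_curtis(rows[i], rows[j])
                assert d.values[i, j] == pytest.approx(expect)

    def test_sample_permutation_equivariance(self):
        rows = [[1, 2, 3], [4, 5, 6], [7, 0, 1]]
        d1 = distance_matrix(table(rows, ["a", "b", "c"]))
        d2 = distance_matrix(table(rows[::-1], ["c", "b", "a"]))
        assert d1[("a", "c")] == pytest.approx(d2[("a", "c")])

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            distance_matrix(table([[1, 2]], ["a"]))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 0.3], [0.2, 0.0]]))


class TestCompleteLinkage:
    def two_sample_matrix(self):
        return DistanceMatrix(["a", "b"], np.array([[0.0, 0.4], [0.4, 0.0]]))

    def test_two_samples_single_merge_at_their_distance(self):
        dend = complete_linkage(self.two_sample_matrix())
        assert len(dend.merges) == 1
        assert dend.merges[0][2] == pytest.approx(0.4)

    def test_three_sample_hand_trace(self):
        vals = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.8], [0.9, 0.8, 0.0]])
        dend = complete_linkage(DistanceMatrix(["A", "B", "C"], vals))
        (a, b, h1), (c, d, h2) = dend.merges
        assert {a, b} == {0, 1} and h1 == pytest.approx(0.1)
        assert h2 == pytest.approx(0.9)  # complete linkage: max(0.9, 0.8)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(3)
        rows = rng.integers(1, 100, size=(8, 12)).astype(float)
        d = distance_matrix(table(rows, [f"s{i}" for i in range(8)]))
        heights = complete_linkage(d).heights
        assert all(h2 >= h1 for h1, h2 in zip(heights, heights[1:]))

    def test_ultrametric_heights_reproduced_exactly(self):
        # ultrametric: d(A,B)=0.2, d(*,C)=0.6
        vals = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
        dend = complete_linkage(DistanceMatrix(["A", "B", "C"], vals))
        assert dend.heights == pytest.approx([0.2, 0.6])

    def test_newick_serialization(self):
        vals = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.8], [0.9, 0.8, 0.0]])
        nwk = complete_linkage(DistanceMatrix(["A", "B", "C"], vals)).to_newick()
        assert nwk.endswith(";")
        assert nwk.count("(") == nwk.count(")") == 2
        import io

        from skbio import TreeNode

        tree = TreeNode.read(io.StringIO(nwk))
        assert {t.name for t in tree.tips()} == {"A", "B", "C"}


class TestShannon:
    def test_uniform_four_features_is_ln4(self):
        assert shannon([1, 1, 1, 1]) == pytest.approx(math.log(4), abs=1e-12)

    def test_single_feature_zero_diversity(self):
        assert shannon([0, 9, 0]) == 0.0

    def test_hand_value(self):
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.5 * math.log(2))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    def test_agrees_with_scipy_entropy(self):
        from scipy.stats import entropy

        x = [5, 1, 7, 2, 9]
        assert shannon(x) == pytest.approx(entropy(np.array(x) / sum(x)))

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=2, max_size=10))
    def test_bounded_by_log_richness(self, x):
        if sum(x) == 0:
            return
        k = len(x)
        h = shannon(x)
        assert h <= math.log(k) + 1e-12
        if len(set(x)) == 1:
            assert h == pytest.approx(math.log(k))


class TestStructureFunction:
    def samples(self):
        rng = np.random.default_rng(11)
        names = [f"s{i}" for i in range(8)]
        taxa = table(rng.integers(1, 200, size=(8, 10)).astype(float), names)
        grouping = {n: ("gut" if i < 4 else "skin") for i, n in enumerate(names)}
        return names, taxa, grouping

    def test_identical_tables_give_perfect_correlation(self):
        names, taxa, grouping = self.samples()
        out = structure_function_correlation(taxa, taxa, grouping)
        assert set(out) == {"gut", "skin"}
        for g in out.values():
            assert g.pearson_r == pytest.approx(1.0)
            assert g.n_pairs == 6

    def test_linear_mixing_with_noise_keeps_high_correlation(self):
        names, taxa, grouping = self.samples()
        rng = np.random.default_rng(5)
        # fixed linear map that relabels and rescales taxon features
        # (each functional trait carried by exactly one lineage), plus small
        # multiplicative noise; Bray-Curtis is preserved up to the noise
        mixing = np.zeros((10, 10))
        for j, i in enumerate(rng.permutation(10)):
            mixing[i, j] = 0.7
        func_rows = taxa.data.to_numpy() @ mixing
        func_rows *= rng.normal(1.0, 0.01, size=func_rows.shape)
        domains = table(func_rows, names)
        out = structure_function_correlation(taxa, domains, grouping)
        for g in out.values():
            assert g.pearson_r > 0.9

    def test_group_of_two_skipped_with_warning(self):
        names, taxa, _ = self.samples()
        grouping = {n: ("tiny" if i < 2 else "rest") for i, n in enumerate(names)}
        with pytest.warns(UserWarning, match="tiny"):
            out = structure_function_correlation(taxa, taxa, grouping)
        assert "tiny" not in out and "rest" in out

    def test_sample_mismatch_rejected(self):
        names, taxa, grouping = self.samples()
        other = table(taxa.data.to_numpy()[:4], names[:4])
        with pytest.raises(ValueError, match="same samples"):
            structure_function_correlation(taxa, other, grouping)
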