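import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform
from scipy import stats

from mitocross import dendro
from mitocross.dendro import (
    Dendrogram,
    DendroError,
    compare_trait_sequence_trees,
    cpcc,
    entanglement,
    hcluster,
    sequence_distance,
    untangle,
)


class TestSequenceDistance:
    def test_identical_and_single_mismatch(self):
        d = sequence_distance({"a": "ACGTACGTAC", "b": "ACGTACGTAC", "c": "ACGTACGTAT"})
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "c"] == pytest.approx(0.1)

    def test_gap_exclusion(self):
        d = sequence_distance({"a": "AC-GT", "b": "ACTGA"})
        assert d.loc["a", "b"] == pytest.approx(0.25)  # 1 mismatch / 4 sites

    def test_unequal_lengths_error(self):
        with pytest.raises(DendroError, match="length"):
            sequence_distance({"a": "ACGT", "b": "ACG"})

    def test_all_gaps_error(self):
        with pytest.raises(DendroError, match="comparable"):
            sequence_distance({"a": "--", "b": "AA"})


class TestHcluster:
    def test_two_items(self):
        d = hcluster(pd.DataFrame([[0.0], [3.0]], index=["a", "b"]))
        assert d.Z[0, 2] == pytest.approx(3.0)

    def test_three_item_average_by_hand(self):
        D = pd.DataFrame(
            [[0, 1, 5], [1, 0, 5], [5, 5, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        d = hcluster(D, metric="precomputed", method="average")
        C = d.cophenetic_matrix()
        assert C.loc["A", "B"] == pytest.approx(1.0)
        assert C.loc["A", "C"] == pytest.approx(5.0)
        assert C.loc["B", "C"] == pytest.approx(5.0)

    @pytest.mark.parametrize("method", ["average", "complete", "ward"])
    def test_matches_scipy_on_random_data(self, method, rng):
        """Cross-check against scipy's linkage via cophenetic matrices."""
        for _ in range(5):
            X = rng.normal(size=(12, 5))
            labels = [f"i{k:02d}" for k in range(12)]
            mine = hcluster(pd.DataFrame(X, index=labels), method=method)
            Z = sch.linkage(X, method=method)
            C1 = mine.cophenetic_matrix().loc[labels, labels].to_numpy()
            C2 = squareform(sch.cophenet(Z))
            np.testing.assert_allclose(C1, C2, rtol=1e-8, atol=1e-10)

    def test_input_order_invariance(self, rng):
        X = rng.normal(size=(9, 4))
        labels = [f"i{k}" for k in range(9)]
        df = pd.DataFrame(X, index=labels)
        a = hcluster(df)
        perm = rng.permutation(9)
        b = hcluster(df.iloc[perm])
        pd.testing.assert_frame_equal(
            a.cophenetic_matrix().loc[labels, labels],
            b.cophenetic_matrix().loc[labels, labels],
        )

    def test_missing_values_rejected(self):
        X = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]], index=["a", "b"])
        with pytest.raises(DendroError, match="missing"):
            hcluster(X)

    def test_ultrametric_cophenetic(self, rng):
        """For average/complete linkage the cophenetic matrix is
        ultrametric: in every triple the max is attained at least twice."""
        X = rng.normal(size=(8, 3))
        d = hcluster(pd.DataFrame(X, index=[f"i{k}" for k in range(8)]))
        C = d.cophenetic_matrix().to_numpy()
        for i, j, k in itertools.combinations(range(8), 3):
            trio = sorted([C[i, j], C[i, k], C[j, k]])
            assert trio[2] == pytest.approx(trio[1], rel=1e-9)


class TestCpcc:
    def make_tree(self, rng, labels):
        X = rng.normal(size=(len(labels), 4))
        return hcluster(pd.DataFrame(X, index=labels))

    def test_self_correlation_is_one(self, rng):
        d = self.make_tree(rng, list("ABCDE"))
        assert cpcc(d, d) == pytest.approx(1.0)

    def test_height_scale_invariance(self, rng):
        d1 = self.make_tree(rng, list("ABCDE"))
        Z2 = d1.Z.copy()
        Z2[:, 2] *= 2.0
        d2 = Dendrogram(labels=list(d1.labels), Z=Z2)
        assert cpcc(d1, d2) == pytest.approx(1.0)

    def test_four_leaf_oracle(self, rng):
        d1 = self.make_tree(rng, list("ABCD"))
        d2 = self.make_tree(rng, list("ABCD"))
        got = cpcc(d1, d2)
        labs = sorted(d1.labels)
        v1, v2 = [], []
        for a, b in itertools.combinations(labs, 2):
            v1.append(d1.cophenetic_matrix().loc[a, b])
            v2.append(d2.cophenetic_matrix().loc[a, b])
        assert got == pytest.approx(stats.pearsonr(v1, v2)[0], rel=1e-10)

    def test_label_mismatch_errors(self, rng):
        d1 = self.make_tree(rng, list("ABCD"))
        d2 = self.make_tree(rng, list("ABCE"))
        with pytest.raises(DendroError, match="label"):
            cpcc(d1, d2)


class TestEntanglement:
    def test_identical_orders_zero(self):
        assert entanglement(list("abcd"), list("abcd")) == 0.0

    def test_full_reversal_one(self):
        assert entanglement(list("abcde"), list("edcba")) == pytest.approx(1.0)

    def test_adjacent_transposition_hand_value(self):
        # n=3, diffs (0,1,1), denominator 2*2^1.5
        got = entanglement(list("abc"), ["a", "c", "b"], L=1.5)
        assert got == pytest.approx(2 / (2 * 2**1.5))
        assert got == pytest.approx(0.35355339, abs=1e-7)

    def test_symmetry_and_relabeling_invariance(self, rng):
        labs = [f"x{i}" for i in range(7)]
        o1 = list(rng.permutation(labs))
        o2 = list(rng.permutation(labs))
        assert entanglement(o1, o2) == pytest.approx(entanglement(o2, o1))
        ren = {l: f"y{i}" for i, l in enumerate(labs)}
        assert entanglement([ren[l] for l in o1], [ren[l] for l in o2]) == pytest.approx(
            entanglement(o1, o2)
        )

    def test_label_mismatch(self):
        with pytest.raises(DendroError):
            entanglement(["a", "b"], ["a", "c"])


class TestUntangle:
    def test_identical_trees_reach_zero(self, rng):
        X = rng.normal(size=(8, 5))
        labs = [f"h{k}" for k in range(8)]
        d1 = hcluster(pd.DataFrame(X, index=labs))
        # second tree: same structure, scrambled input order
        d2 = hcluster(pd.DataFrame(X, index=labs).iloc[rng.permutation(8)])
        st = untangle(d1, d2)
        assert st.entanglement == pytest.approx(0.0, abs=1e-12)
        assert st.exhaustive_entanglement == pytest.approx(0.0, abs=1e-12)

    def test_greedy_never_beats_exhaustive(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            labs = [f"h{k}" for k in range(n)]
            d1 = hcluster(pd.DataFrame(rng.normal(size=(n, 3)), index=labs))
            d2 = hcluster(pd.DataFrame(rng.normal(size=(n, 3)), index=labs))
            st = untangle(d1, d2)
            assert st.entanglement >= st.exhaustive_entanglement - 1e-12

    def test_four_leaf_fixture_matches_exhaustive(self):
        D1 = pd.DataFrame(
            [[0, 1, 4, 4.5], [1, 0, 4.2, 4.6], [4, 4.2, 0, 1.5], [4.5, 4.6, 1.5, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        D2 = pd.DataFrame(
            [[0, 3, 1, 4], [3, 0, 3.5, 1.2], [1, 3.5, 0, 4.1], [4, 1.2, 4.1, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        d1 = hcluster(D1, metric="precomputed")
        d2 = hcluster(D2, metric="precomputed")
        st = untangle(d1, d2)
        assert st.entanglement == pytest.approx(st.exhaustive_entanglement, abs=1e-12)

    def test_deterministic(self, rng):
        labs = [f"h{k}" for k in range(7)]
        d1 = hcluster(pd.DataFrame(rng.normal(size=(7, 3)), index=labs))
        d2 = hcluster(pd.DataFrame(rng.normal(size=(7, 3)), index=labs))
        a = untangle(d1, d2)
        b = untangle(d1, d2)
        assert a.order1 == b.order1 and a.order2 == b.order2
        assert a.entanglement == b.entanglement


class TestCompareTraitSequence:
    def test_identical_structure_gives_perfect_stats(self, rng):
        labs = list("ABCDEFGH")
        M = pd.DataFrame(rng.normal(size=(8, 5)), index=labs,
                         columns=[f"t{i}" for i in range(5)])
        z = (M - M.mean()) / M.std(ddof=1)
        from scipy.spatial.distance import pdist

        D = pd.DataFrame(squareform(pdist(z.to_numpy())), index=labs, columns=labs)
        st = compare_trait_sequence_trees(M, D)
        assert st.entanglement == pytest.approx(0.0, abs=1e-12)
        assert st.cpcc == pytest.approx(1.0, abs=1e-9)

    def test_random_traits_cpcc_centered(self, rng):
        labs = list("ABCDEFGH")
        D = pd.DataFrame(
            squareform(np.abs(rng.normal(size=28)) + 0.5), index=labs, columns=labs
        )
        vals = []
        for _ in range(60):
            M = pd.DataFrame(rng.normal(size=(8, 6)), index=labs)
            M.columns = [f"t{i}" for i in range(6)]
            vals.append(compare_trait_sequence_trees(M, D).cpcc)
        assert abs(np.mean(vals)) < 0.2

    def test_too_few_shared_labels(self, rng):
        M = pd.DataFrame(rng.normal(size=(2, 3)), index=["A", "B"])
        D = pd.DataFrame(np.zeros((2, 2)), index=["A", "B"], columns=["A", "B"])
        with pytest.raises(DendroError, match="shared"):
            compare_trait_sequence_trees(M, D)


def test_newick_round_trip_preserves_cophenetic(rng, tmp_path):
    """Serialised trees re-parse to the same cophenetic structure."""
    import io

    from Bio import Phylo

    labs = [f"h{k}" for k in range(6)]
    d = hcluster(pd.DataFrame(rng.normal(size=(6, 4)), index=labs))
    tree = Phylo.read(io.StringIO(d.to_newick()), "newick")
    depths = tree.depths()
    root_h = d.Z[-1, 2]
    C = d.cophenetic_matrix()
    terms = {t.name: t for t in tree.get_terminals()}
    for a, b in itertools.combinations(labs, 2):
        mrca = tree.common_ancestor([terms[a], terms[b]])
        merge_h = root_h - depths[mrca]
        assert merge_h == pytest.approx(C.loc[a, b], abs=1e-6)
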