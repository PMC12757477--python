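"""ORA with brute-force hypergeometric oracle, bubble-term selection and
TF-target matrix clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from phosphodiff import enrichment as en
from phosphodiff.model import ValidationError


def exhaustive_tail(N: int, K: int, n: int, k: int) -> float:
    """P[X >= k] by enumerating every n-subset of an N-universe."""
    universe = list(range(N))
    annotated = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(annotated & set(draw)) >= k:
            hits += 1
    return hits / total


class TestOra:
    def _collection(self, sets):
        return en.GeneSetCollection(sets={k: set(v) for k, v in sets.items()},
                                    source_db={k: "db" for k in sets})

    def test_perfect_five_gene_set_in_universe_of_ten(self):
        universe = {f"g{i}" for i in range(10)}
        query = {f"g{i}" for i in range(5)}
        col = self._collection({"s": query})
        row = en.ora(query, col, universe).iloc[0]
        assert row["p_raw"] == pytest.approx(1 / math.comb(10, 5))
        assert row["p_raw"] == pytest.approx(1 / 252, rel=1e-12)

    def test_matches_exhaustive_enumeration_small_universes(self):
        from scipy.stats import hypergeom
        for N, K, n in [(8, 3, 4), (10, 5, 5), (12, 6, 4), (9, 2, 3)]:
            for k in range(1, min(K, n) + 1):
                assert hypergeom.sf(k - 1, N, K, n) == pytest.approx(
                    exhaustive_tail(N, K, n, k), rel=1e-9), (N, K, n, k)

    def test_zero_overlap_sets_excluded(self):
        universe = {f"g{i}" for i in range(10)}
        col = self._collection({"hit": {"g0", "g1"}, "miss": {"g8", "g9"}})
        out = en.ora({"g0", "g1", "g2"}, col, universe)
        assert out["set_name"].tolist() == ["hit"]

    def test_query_equal_universe_saturates_p(self):
        universe = {f"g{i}" for i in range(8)}
        col = self._collection({"s1": {"g0", "g1"}, "s2": {"g3"}})
        out = en.ora(set(universe), col, universe)
        assert np.allclose(out["p_raw"], 1.0)

    def test_empty_query_after_filter_is_error(self):
        col = self._collection({"s": {"g0"}})
        with pytest.raises(ValidationError):
            en.ora({"x"}, col, {"g0", "g1"})


class TestBubbleSelection:
    def _rows(self, entries):
        df = pd.DataFrame(entries, columns=["set_name", "source_db", "p_raw",
                                            "p_adj", "K", "overlap_genes"])
        df["k"] = df["overlap_genes"].str.count(",") + 1
        df["n"], df["N"] = 5, 100
        return df

    def test_same_name_keeps_smallest_p(self):
        rows = self._rows([("term", "go", 0.01, 0.01, 10, "a,b"),
                           ("term", "bioplanet", 0.02, 0.03, 12, "a,b")])
        out = en.select_bubble_terms(rows)
        assert len(out) == 1 and out.iloc[0]["p_adj"] == 0.01

    def test_identical_member_sets_keep_larger_K(self):
        rows = self._rows([("small", "go", 0.01, 0.01, 8, "a,b,c"),
                           ("general", "go", 0.02, 0.02, 30, "a,b,c")])
        out = en.select_bubble_terms(rows)
        assert out["set_name"].tolist() == ["general"]

    def test_disjoint_terms_both_kept(self):
        rows = self._rows([("t1", "go", 0.01, 0.01, 10, "a,b"),
                           ("t2", "go", 0.02, 0.02, 10, "c,d")])
        assert len(en.select_bubble_terms(rows)) == 2

    def test_output_subset_sorted_and_shuffle_stable(self, rng):
        rows = self._rows([(f"t{i}", "go", 0.001 * (i + 1), 0.002 * (i + 1), 10 + i,
                            ",".join(f"g{i}{j}" for j in range(3)))
                           for i in range(8)])
        out1 = en.select_bubble_terms(rows)
        out2 = en.select_bubble_terms(rows.sample(frac=1, random_state=4))
        assert out1["set_name"].tolist() == out2["set_name"].tolist()
        assert set(out1["set_name"]) <= set(rows["set_name"])
        assert (out1["p_adj"].diff().dropna() >= 0).all()

    def test_exclusion_list_applied(self):
        rows = self._rows([("keep", "go", 0.01, 0.01, 10, "a"),
                           ("drop_me", "go", 0.02, 0.02, 10, "b")])
        out = en.select_bubble_terms(rows, exclude={"drop_me"})
        assert out["set_name"].tolist() == ["keep"]


class TestTfMatrix:
    def test_incidence_construction_and_unregulated_gene_dropped(self):
        m = en.build_tf_matrix(["g1", "g2", "g3"],
                               [("tf1", "g1"), ("tf1", "g2"), ("tf2", "g2")],
                               expressed_filter={"tf1", "tf2"})
        assert m.cells.index.tolist() == ["g1", "g2"]
        assert m.cells.loc["g1"].tolist() == [1, 0]
        assert m.cells.loc["g2"].tolist() == [1, 1]
        assert m.dropped_genes == ["g3"]

    def test_unexpressed_tf_column_absent(self):
        m = en.build_tf_matrix(["g1"], [("tf1", "g1"), ("ghost", "g1")],
                               expressed_filter={"tf1"})
        assert m.cells.columns.tolist() == ["tf1"]
        assert m.dropped_tfs == ["ghost"]

    def test_duplicate_edges_idempotent(self):
        edges = [("tf1", "g1"), ("tf1", "g1"), ("tf2", "g2")]
        m1 = en.build_tf_matrix(["g1", "g2"], edges, {"tf1", "tf2"})
        m2 = en.build_tf_matrix(["g1", "g2"], edges[1:], {"tf1", "tf2"})
        pd.testing.assert_frame_equal(m1.cells, m2.cells)

    def test_no_surviving_tf_is_error(self):
        with pytest.raises(ValidationError):
            en.build_tf_matrix(["g1"], [("tf1", "g1")], expressed_filter=set())


def _block_matrix(n_genes=12, n_tfs=6, flip=0):
    """Two clean gene blocks regulated by two disjoint TF groups."""
    genes = [f"g{i:02d}" for i in range(n_genes)]
    tfs = [f"tf{j}" for j in range(n_tfs)]
    cells = pd.DataFrame(0, index=genes, columns=tfs, dtype=int)
    half_g, half_t = n_genes // 2, n_tfs // 2
    cells.iloc[:half_g, :half_t] = 1
    cells.iloc[half_g:, half_t:] = 1
    if flip:
        cells.iloc[0, -1] = 1  # a little asymmetry, still two blocks
    return en.TFTargetMatrix(cells=cells)


class TestTwoWayCluster:
    def test_two_blocks_recovered_exactly(self):
        m = _block_matrix()
        res = en.two_way_cluster(m, k_gene_clusters=2)
        labels = res.gene_clusters
        first = set(labels.index[labels == labels.iloc[0]])
        assert first in ({f"g{i:02d}" for i in range(6)},
                         {f"g{i:02d}" for i in range(6, 12)})

    def test_permutation_invariance_up_to_label_swap(self, rng):
        m = _block_matrix(flip=1)
        perm = rng.permutation(m.cells.index)
        m_perm = en.TFTargetMatrix(cells=m.cells.loc[perm])
        r1 = en.two_way_cluster(m, 2).gene_clusters.sort_index()
        r2 = en.two_way_cluster(m_perm, 2).gene_clusters.sort_index()
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(r1.to_numpy(), r2.to_numpy()) == 1.0
        assert r1.index.tolist() == r2.index.tolist()

    def test_constant_matrix_is_error(self):
        genes = [f"g{i}" for i in range(4)]
        cells = pd.DataFrame(1, index=genes, columns=["tf1", "tf2"])
        with pytest.raises(ValidationError, match="no structure"):
            en.two_way_cluster(en.TFTargetMatrix(cells=cells))

    def test_too_small_matrix_rejected(self):
        cells = pd.DataFrame([[1, 0], [0, 1]], index=["g1", "g2"],
                             columns=["tf1", "tf2"])
        with pytest.raises(ValidationError):
            en.two_way_cluster(en.TFTargetMatrix(cells=cells))
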