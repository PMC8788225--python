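import numpy as np
import pandas as pd
import pytest

from evoprofiler.data_model_io import ExpressionMap, ExpressionMatrix, GeneCatalog
from evoprofiler.expression_similarity import (
    cooccurrence_permutation_test,
    cooccurrence_score,
    cooccurrence_table,
    evo_expr_pairing,
    export_similarity_graph,
    expression_partition_from_matrix,
    family_cell_sets,
    module_cooccurrence,
    occupied_cells,
    occupied_supercells,
)


def _catalog(fams):
    return GeneCatalog(
        assignments={g: (f, "S") for f, genes in fams.items() for g in genes}
    )


class TestFamilyCellSets:
    def test_toroidal_wraparound(self):
        emap = ExpressionMap(5, 5, {"g1": (0, 0)})
        sc = occupied_supercells(emap, ["g1"])
        assert (4, 4) in sc and (0, 1) in sc and (4, 0) in sc

    def test_single_gene_counts(self):
        emap = ExpressionMap(5, 5, {"g1": (2, 2)})
        assert len(occupied_cells(emap, ["g1"])) == 1
        assert len(occupied_supercells(emap, ["g1"])) == 9

    def test_supercell_matches_bruteforce_dilation(self, rng):
        rows, cols = 7, 6
        genes = {f"g{i}": (int(rng.integers(rows)), int(rng.integers(cols)))
                 for i in range(20)}
        emap = ExpressionMap(rows, cols, genes)
        fast = occupied_supercells(emap, list(genes))
        # naive 3x3 scan: supercell center c is occupied if any gene lies in
        # the 3x3 toroidal block around c
        slow = set()
        cells = set(genes.values())
        for r in range(rows):
            for c in range(cols):
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if ((r + dr) % rows, (c + dc) % cols) in cells:
                            slow.add((r, c))
        assert fast == slow

    def test_nontoroidal_no_wrap(self):
        emap = ExpressionMap(5, 5, {"g1": (0, 0)}, toroidal=False)
        sc = occupied_supercells(emap, ["g1"])
        assert (4, 4) not in sc
        assert len(sc) == 4


class TestScore:
    def test_identical_sets(self):
        assert cooccurrence_score({1, 2}, {1, 2}) == 1.0

    def test_disjoint_sets(self):
        assert cooccurrence_score({1}, {2}) == 0.0

    def test_jaccard_arithmetic(self):
        assert cooccurrence_score({1, 2, 3}, {3, 4}) == pytest.approx(1 / 4)

    def test_empty_missing(self):
        assert np.isnan(cooccurrence_score(set(), {1}))


class TestPermutationTest:
    def test_planted_signal_low_p(self):
        rng = np.random.default_rng(0)
        cells = {}
        # two families planted in the same 3 cells of a 10x10 map
        shared = [(0, 0), (5, 5), (9, 2)]
        fams = {"FA": [f"a{i}" for i in range(8)],
                "FB": [f"b{i}" for i in range(8)]}
        for fam, genes in fams.items():
            for g in genes:
                cells[g] = shared[rng.integers(3)]
        for i in range(200):
            cells[f"bg{i}"] = (int(rng.integers(10)), int(rng.integers(10)))
        emap = ExpressionMap(10, 10, cells)
        obs, p = cooccurrence_permutation_test(
            emap, _catalog(fams), ("FA", "FB"), n_perm=2000, seed=1
        )
        assert obs == 1.0
        assert p <= 0.01

    def test_marginals_preserved(self):
        from evoprofiler.expression_similarity import _map_arrays

        rng = np.random.default_rng(2)
        cells = {f"g{i}": (int(rng.integers(4)), int(rng.integers(4)))
                 for i in range(30)}
        emap = ExpressionMap(4, 4, cells)
        arrays = _map_arrays(emap)
        perms = rng.permuted(
            np.broadcast_to(arrays.assignment, (50, 30)).copy(), axis=1
        )
        base = np.bincount(arrays.assignment, minlength=16)
        for row in perms:
            assert np.array_equal(np.bincount(row, minlength=16), base)

    def test_null_calibration_small(self):
        """Scaled-down type-I calibration; full size in acceptance tests."""
        rng = np.random.default_rng(3)
        rejections = 0
        n_sims = 200
        fams = {"FA": [f"a{i}" for i in range(6)],
                "FB": [f"b{i}" for i in range(6)]}
        catalog = _catalog(fams)
        for sim in range(n_sims):
            cells = {}
            for g in [*fams["FA"], *fams["FB"], *[f"bg{i}" for i in range(60)]]:
                cells[g] = (int(rng.integers(8)), int(rng.integers(8)))
            emap = ExpressionMap(8, 8, cells)
            _, p = cooccurrence_permutation_test(
                emap, catalog, ("FA", "FB"), n_perm=199,
                rng=rng,
            )
            rejections += p < 0.05
        assert 0.005 <= rejections / n_sims <= 0.12

    def test_supercell_implies_cell_subset(self):
        rng = np.random.default_rng(4)
        cells = {f"g{i}": (int(rng.integers(6)), int(rng.integers(6)))
                 for i in range(40)}
        fams = {"FA": [f"g{i}" for i in range(10)],
                "FB": [f"g{i}" for i in range(10, 20)]}
        emap = ExpressionMap(6, 6, cells)
        catalog = _catalog(fams)
        sets_cell = family_cell_sets(emap, catalog, "cell")
        sets_super = family_cell_sets(emap, catalog, "supercell")
        inter_cell = sets_cell["FA"] & sets_cell["FB"]
        inter_super = sets_super["FA"] & sets_super["FB"]
        if inter_cell:
            assert inter_super


class TestModuleCooccurrence:
    def test_single_shared_module_score_one(self):
        fams = {"FA": ["a1", "a2"], "FB": ["b1"]}
        partition = {"a1": "m1", "a2": "m1", "b1": "m1"}
        table = module_cooccurrence(partition, _catalog(fams), n_perm=100, seed=1)
        assert table.loc[0, "score"] == 1.0
        assert (table["resolution"] == "module").all()

    def test_disjoint_modules_zero(self):
        fams = {"FA": ["a1"], "FB": ["b1"]}
        partition = {"a1": "m1", "b1": "m2"}
        table = module_cooccurrence(partition, _catalog(fams), n_perm=100, seed=1)
        assert table.loc[0, "score"] == 0.0

    def test_reduces_to_cell_resolution(self):
        rng = np.random.default_rng(5)
        cells = {f"g{i}": (0, int(rng.integers(6))) for i in range(30)}
        fams = {"FA": [f"g{i}" for i in range(8)],
                "FB": [f"g{i}" for i in range(8, 16)]}
        catalog = _catalog(fams)
        emap = ExpressionMap(1, 6, cells, toroidal=False)
        cell_table = cooccurrence_table(emap, catalog, "cell", n_perm=500, seed=9)
        partition = {g: f"m{c[1]}" for g, c in cells.items()}
        mod_table = module_cooccurrence(partition, catalog, n_perm=500, seed=9)
        assert cell_table.loc[0, "score"] == pytest.approx(mod_table.loc[0, "score"])
        assert cell_table.loc[0, "p_value"] == pytest.approx(
            mod_table.loc[0, "p_value"]
        )


class TestExpressionPartition:
    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(6)
        n = 30
        block1 = rng.normal(0, 0.3, size=(n, 10)) + np.linspace(-3, 3, 10)
        block2 = rng.normal(0, 0.3, size=(n, 10)) - np.linspace(-3, 3, 10)
        values = pd.DataFrame(
            np.vstack([block1, block2]),
            index=[f"g{i}" for i in range(2 * n)],
            columns=[f"c{i}" for i in range(10)],
        )
        partition = expression_partition_from_matrix(
            ExpressionMatrix(values=values), n_modules=2
        )
        mods1 = {partition[f"g{i}"] for i in range(n)}
        mods2 = {partition[f"g{i}"] for i in range(n, 2 * n)}
        assert len(mods1) == 1 and len(mods2) == 1 and mods1 != mods2

    def test_constant_genes_unclustered(self):
        values = pd.DataFrame(
            [[1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [2.0, 1.0, 0.0]],
            index=["flat", "up", "down"], columns=["c1", "c2", "c3"],
        )
        partition = expression_partition_from_matrix(
            ExpressionMatrix(values=values), n_modules=2
        )
        assert partition["flat"].startswith("unclustered")

    def test_module_count_equals_k(self, rng):
        values = pd.DataFrame(
            rng.normal(size=(20, 8)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"c{i}" for i in range(8)],
        )
        partition = expression_partition_from_matrix(
            ExpressionMatrix(values=values), n_modules=4
        )
        assert len(set(partition.values())) == 4

    def test_too_few_conditions_rejected(self):
        values = pd.DataFrame({"c1": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.raises(Exception):
            expression_partition_from_matrix(ExpressionMatrix(values=values))


class TestPairingAndGraph:
    def _tables(self):
        evo = pd.DataFrame(
            [[1.0, 0.8, 0.1], [0.8, 1.0, 0.2], [0.1, 0.2, 1.0]],
            index=["FA", "FB", "FC"], columns=["FA", "FB", "FC"],
        )
        expr = pd.DataFrame(
            [
                {"family1": "FA", "family2": "FB", "score": 0.9,
                 "p_value": 0.004, "resolution": "cell", "n_perm": 100, "seed": 1},
                {"family1": "FA", "family2": "FC", "score": 0.1,
                 "p_value": 0.5, "resolution": "cell", "n_perm": 100, "seed": 1},
                {"family1": "FB", "family2": "FX", "score": 0.2,
                 "p_value": 0.3, "resolution": "cell", "n_perm": 100, "seed": 1},
            ]
        )
        return evo, expr

    def test_pairs_absent_excluded(self):
        evo, expr = self._tables()
        paired = evo_expr_pairing(evo, expr)
        assert len(paired) == 2  # FX not in evo matrix
        assert set(zip(paired["family1"], paired["family2"])) == {
            ("FA", "FB"), ("FA", "FC")
        }

    def test_significance_flag(self):
        evo, expr = self._tables()
        paired = evo_expr_pairing(evo, expr)
        flags = dict(zip(paired["family2"], paired["significant"]))
        assert flags["FB"] and not flags["FC"]

    def test_complete_inputs_full_pair_count(self):
        evo = pd.DataFrame(np.eye(4), index=list("ABCD"), columns=list("ABCD"))
        rows = []
        fams = list("ABCD")
        for i, a in enumerate(fams):
            for b in fams[i + 1:]:
                rows.append({"family1": a, "family2": b, "score": 0.5,
                             "p_value": 0.5, "resolution": "cell",
                             "n_perm": 10, "seed": 1})
        paired = evo_expr_pairing(evo, pd.DataFrame(rows))
        assert len(paired) == 6

    def test_graph_export_dot(self, tmp_path):
        _, expr = self._tables()
        p = tmp_path / "g.dot"
        export_similarity_graph(expr, p, all_families=["FA", "FB", "FC", "FX"])
        text = p.read_text()
        assert '"FA" -- "FB"' in text
        assert "p<0.005" in text
        assert '"FA" -- "FC"' not in text

    def test_graph_export_graphml_empty(self, tmp_path):
        table = pd.DataFrame(columns=["family1", "family2", "score", "p_value"])
        p = tmp_path / "g.graphml"
        fams = [f"F{i}" for i in range(36)]
        export_similarity_graph(table, p, fmt="graphml", all_families=fams)
        import networkx as nx

        G = nx.read_graphml(p)
        assert G.number_of_nodes() == 36
        assert G.number_of_edges() == 0

    def test_edge_count_matches_significant_rows(self, tmp_path):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(30):
            rows.append({"family1": f"A{i}", "family2": f"B{i}",
                         "score": 0.5, "p_value": float(rng.uniform())})
        table = pd.DataFrame(rows)
        p = tmp_path / "g.dot"
        export_similarity_graph(table, p)
        n_edges = p.read_text().count(" -- ")
        assert n_edges == (table["p_value"] < 0.05).sum()


class TestHypothesisProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.sets(st.integers(0, 30), min_size=1, max_size=15),
        st.sets(st.integers(0, 30), min_size=1, max_size=15),
    )
    @settings(max_examples=100, deadline=None)
    def test_score_bounds_and_symmetry(self, a, b):
        s = cooccurrence_score(a, b)
        assert 0.0 <= s <= 1.0
        assert s == cooccurrence_score(b, a)
        if a == b:
            assert s == 1.0
        if not (a & b):
            assert s == 0.0
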