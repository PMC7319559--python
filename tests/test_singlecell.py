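"""Single-cell filtering, normalization, per-cell ORA, group characterization."""

import numpy as np
import pytest
from scipy import sparse

from trailkit.fixtures import make_singlecell_fixture
from trailkit.geneset import GeneSetCollection, read_gmt
from trailkit.singlecell import (
    CellMatrix,
    characterize_groups,
    expressed_set,
    filter_cells,
    normalize,
    percell_enrichment,
    read_annotation,
    read_dense,
    read_mtx,
)


def _matrix(dense, genes=None, cells=None):
    dense = np.asarray(dense, dtype=float)
    genes = genes or [f"g{i}" for i in range(dense.shape[0])]
    cells = cells or [f"c{i}" for i in range(dense.shape[1])]
    return CellMatrix(genes=genes, cells=cells, counts=sparse.csr_matrix(dense))


class TestReaders:
    def test_mtx_roundtrip_with_duplicates(self, tmp_path):
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n"
            "2 2 3\n1 1 2\n1 1 3\n2 2 4\n"
        )
        (tmp_path / "genes.txt").write_text("gA\ngB\n")
        (tmp_path / "cells.txt").write_text("c1\nc2\n")
        m = read_mtx(tmp_path / "m.mtx", tmp_path / "genes.txt", tmp_path / "cells.txt")
        dense = m.counts.toarray()
        assert dense[0, 0] == 5  # duplicate entries summed
        assert dense[1, 1] == 4

    def test_mtx_dimension_mismatch(self, tmp_path):
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n2 2 1\n1 1 1\n"
        )
        (tmp_path / "genes.txt").write_text("gA\n")
        (tmp_path / "cells.txt").write_text("c1\nc2\n")
        with pytest.raises(ValueError, match="dimensions"):
            read_mtx(tmp_path / "m.mtx", tmp_path / "genes.txt", tmp_path / "cells.txt")

    def test_dense_reader(self, tmp_path):
        (tmp_path / "m.tsv").write_text("\tc1\tc2\ngA\t1\t0\ngB\t0\t2\n")
        m = read_dense(tmp_path / "m.tsv")
        assert m.genes == ["gA", "gB"] and m.cells == ["c1", "c2"]
        assert m.counts.toarray().tolist() == [[1, 0], [0, 2]]

    def test_annotation_requires_cell_id(self, tmp_path):
        (tmp_path / "ann.tsv").write_text("cell\tgroup\nc1\ta\n")
        with pytest.raises(ValueError, match="cell_id"):
            read_annotation(tmp_path / "ann.tsv")


class TestFilterCells:
    def test_min_genes_drops_empty_cells(self):
        m = _matrix([[0, 5], [0, 3], [0, 2]])
        filtered, dropped = filter_cells(m, min_genes=2, max_count_mads=np.inf)
        assert dropped == ["c0"]
        assert filtered.cells == ["c1"]

    def test_infinite_mads_disables_doublet_filter(self):
        m = _matrix([[1, 1000], [1, 1000]])
        filtered, dropped = filter_cells(m, min_genes=0, max_count_mads=np.inf)
        assert dropped == []

    def test_planted_doublet_detected(self):
        # totals constructed so only the doubled cell exceeds median + 3*MAD
        counts = np.full((50, 40), 5.0)
        counts[0, :] += np.linspace(0, 4, 40)  # mild spread in totals
        counts[:, 7] *= 2  # a doubled-count doublet
        m = _matrix(counts)
        _, dropped = filter_cells(m, min_genes=0, max_count_mads=3.0)
        assert dropped == ["c7"]

    def test_all_dropped_errors(self):
        m = _matrix([[0], [0]])
        with pytest.raises(ValueError, match="all cells"):
            filter_cells(m, min_genes=1)


class TestNormalize:
    def test_formula_single_gene_cell(self):
        m = _matrix([[5, 1], [0, 1]])
        norm = normalize(m, scale=1e4).normalized.toarray()
        assert norm[0, 0] == pytest.approx(np.log1p(1e4))
        assert norm[1, 0] == 0.0

    def test_depth_invariance(self):
        m1 = _matrix([[2, 0], [4, 1]])
        m2 = _matrix([[4, 0], [8, 1]])  # first cell doubled
        n1 = normalize(m1).normalized.toarray()[:, 0]
        n2 = normalize(m2).normalized.toarray()[:, 0]
        np.testing.assert_allclose(n1, n2)

    def test_zero_total_cell_errors(self):
        m = _matrix([[0, 1], [0, 1]])
        with pytest.raises(ValueError, match="zero total"):
            normalize(m)


class TestExpressedSet:
    def test_nonzero_mode(self):
        m = _matrix([[1, 0], [0, 2], [3, 0]], genes=["A", "B", "C"])
        assert expressed_set(m, "c0") == {"A", "C"}

    def test_top_k_ties_lexicographic(self):
        m = _matrix([[1, 1], [1, 1], [1, 1]], genes=["C", "A", "B"])
        m = normalize(m, scale=10)
        assert expressed_set(m, "c0", mode="top_k", k=2) == {"A", "B"}

    def test_top_k_bounds(self):
        m = _matrix([[1], [1]])
        with pytest.raises(ValueError, match="exceeds"):
            expressed_set(m, "c0", mode="top_k", k=3)
        with pytest.raises(KeyError):
            expressed_set(m, "nope")


class TestPerCellEnrichment:
    def test_cell_matching_category_minimizes_p(self):
        genes = [f"g{i}" for i in range(50)]
        counts = np.zeros((50, 3))
        counts[:10, 0] = 1  # cell 0 expresses exactly the category
        counts[20:45, 1] = 1
        counts[5:30, 2] = 1
        m = CellMatrix(genes, ["c0", "c1", "c2"], sparse.csr_matrix(counts))
        coll = GeneSetCollection(
            "t",
            {"cat": ("", frozenset(genes[:10])), "other": ("", frozenset(genes[30:40]))},
            frozenset(genes),
        )
        res = percell_enrichment(m, coll)
        i_cat = res.categories.index("cat")
        assert res.p_adjusted[0, i_cat] == res.p_adjusted[0].min()
        assert res.enriched[0, i_cat]

    def test_disjoint_category_never_enriched(self):
        genes = [f"g{i}" for i in range(20)]
        counts = np.zeros((20, 2))
        counts[:5, 0] = 1
        counts[5:10, 1] = 1
        m = CellMatrix(genes, ["c0", "c1"], sparse.csr_matrix(counts))
        coll = GeneSetCollection("t", {"cat": ("", frozenset(genes[15:]))}, frozenset(genes))
        res = percell_enrichment(m, coll)
        assert not res.enriched.any()
        np.testing.assert_allclose(res.p_adjusted, 1.0)

    def test_alpha_zero_no_calls(self):
        genes = [f"g{i}" for i in range(20)]
        counts = np.zeros((20, 1))
        counts[:10, 0] = 1
        m = CellMatrix(genes, ["c0"], sparse.csr_matrix(counts))
        coll = GeneSetCollection("t", {"cat": ("", frozenset(genes[:10]))}, frozenset(genes))
        res = percell_enrichment(m, coll, alpha=0.0)
        assert not res.enriched.any()

    def test_purity_depends_only_on_own_expressed_set(self):
        rng = np.random.default_rng(1)
        counts = (rng.random((30, 6)) < 0.3).astype(float)
        counts[:, 0] = 0
        counts[:8, 0] = 1
        genes = [f"g{i}" for i in range(30)]
        coll = GeneSetCollection("t", {"cat": ("", frozenset(genes[:8]))}, frozenset(genes))
        m1 = CellMatrix(genes, [f"c{i}" for i in range(6)], sparse.csr_matrix(counts))
        shuffled = counts.copy()
        shuffled[:, 1:] = shuffled[:, rng.permutation(5) + 1]
        m2 = CellMatrix(genes, [f"c{i}" for i in range(6)], sparse.csr_matrix(shuffled))
        r1 = percell_enrichment(m1, coll)
        r2 = percell_enrichment(m2, coll)
        np.testing.assert_allclose(r1.p_adjusted[0], r2.p_adjusted[0])


class TestCharacterizeGroups:
    def _fixture_calls(self, tmp_path, **kwargs):
        fx = make_singlecell_fixture(
            tmp_path,
            groups_with_sizes={"young": 100, "old": 100},
            n_genes=500,
            seed=2,
            **kwargs,
        )
        m = read_mtx(fx.matrix_path, fx.genes_path, fx.cells_path)
        m, _ = filter_cells(m, min_genes=0, max_count_mads=np.inf)
        coll = read_gmt(fx.gmt_path)
        coll = GeneSetCollection(coll.name, coll.categories, frozenset(m.genes))
        calls = percell_enrichment(m, coll)
        ann = read_annotation(fx.annotation_path)
        return fx, calls, ann

    def test_planted_category_top_ranked_active(self, tmp_path):
        fx, calls, ann = self._fixture_calls(tmp_path)
        results = characterize_groups(calls, ann, "age_group")
        for group, planted_cat in fx.truth.items():
            active = [
                r for r in results
                if r.group[1] == group and r.call == "predominantly_active"
            ]
            assert active, f"no predominantly_active calls for {group}"
            assert active[0].category_id == planted_cat

    def test_contingency_conservation(self, tmp_path):
        _, calls, ann = self._fixture_calls(tmp_path)
        results = characterize_groups(calls, ann, "age_group")
        for r in results:
            assert sum(r.table) == len(calls.cells)

    def test_identical_rates_not_significant(self):
        # both groups enriched at the same rate -> chi2 ~ 0, ns
        enriched = np.zeros((40, 1), dtype=bool)
        enriched[:10] = True  # 50% of each group
        enriched[20:30] = True
        calls_cells = [f"c{i}" for i in range(40)]
        from trailkit.singlecell import PerCellEnrichment

        calls = PerCellEnrichment(calls_cells, ["cat"], np.ones((40, 1)), enriched, 0.05)
        import pandas as pd

        ann = pd.DataFrame(
            {"cell_id": calls_cells, "grp": ["a"] * 20 + ["b"] * 20}
        ).set_index("cell_id")
        results = characterize_groups(calls, ann, "grp")
        assert all(r.call == "ns" for r in results)
        assert all(r.chi2 == pytest.approx(0.0) for r in results)

    def test_missing_annotation_errors(self, tmp_path):
        _, calls, ann = self._fixture_calls(tmp_path)
        with pytest.raises(ValueError, match="not found"):
            characterize_groups(calls, ann, "tissue")
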