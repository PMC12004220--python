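"""Module filters, top-gene extraction and activity scores."""

import numpy as np
import pytest

from coexmod import (
    ExpressionMatrix,
    LOGNORM,
    ModuleSet,
    ParameterError,
    filter_cluster_size,
    filter_module_sd,
    filter_nb_supporting_cells,
    module_activity_scores,
    top_genes,
)


def _expr(values, gene_ids=None, cell_ids=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    cell_ids = cell_ids or [f"c{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(gene_ids, cell_ids, values, LOGNORM)


def _random_modules(rng, gene_ids, n_modules=4):
    pool = list(gene_ids)
    rng.shuffle(pool)
    sizes = rng.integers(1, 6, size=n_modules)
    lists, start = [], 0
    for s in sizes:
        lists.append(pool[start : start + int(s)])
        start += int(s)
    return ModuleSet.from_gene_lists([l for l in lists if l])


class TestClusterSizeFilter:
    def test_quoted_threshold_behavior(self):
        ms = ModuleSet.from_gene_lists(
            [[f"a{i}" for i in range(12)], [f"b{i}" for i in range(10)], [f"c{i}" for i in range(9)]]
        )
        out = filter_cluster_size(ms, 10)
        assert sorted(len(g) for g in out.gene_lists()) == [10, 12]

    def test_min_size_one_is_identity_on_contents(self):
        ms = ModuleSet.from_gene_lists([["a", "b"], ["c"]])
        out = filter_cluster_size(ms, 1)
        assert out.modules == ms.modules

    def test_matches_bruteforce_size_scan(self, rng):
        ms = _random_modules(rng, [f"g{i:02d}" for i in range(40)])
        out = filter_cluster_size(ms, 3)
        expected = sorted(tuple(g) for g in ms.gene_lists() if len(g) >= 3)
        assert sorted(tuple(g) for g in out.gene_lists()) == expected


class TestSupportingCellsFilter:
    def _module_matrix(self):
        # 10-gene module; 5 cells each express exactly 2 genes (fraction 0.2)
        values = np.zeros((10, 5))
        for c in range(5):
            values[2 * c % 10, c] = 1.0
            values[(2 * c + 1) % 10, c] = 1.0
        return _expr(values), ModuleSet({"M01": [f"g{i}" for i in range(10)]})

    def test_kept_at_inclusive_threshold(self):
        m, ms = self._module_matrix()
        out = filter_nb_supporting_cells(ms, m, min_cells=5, min_frac=0.2)
        assert out.n_modules == 1

    def test_removed_when_fraction_raised(self):
        m, ms = self._module_matrix()
        out = filter_nb_supporting_cells(ms, m, min_cells=5, min_frac=0.35)
        assert out.n_modules == 0

    def test_strict_comparison_excludes_boundary(self):
        m, ms = self._module_matrix()
        out = filter_nb_supporting_cells(ms, m, min_cells=1, min_frac=0.2, strict=True)
        assert out.n_modules == 0

    def test_zero_thresholds_keep_everything(self, rng):
        values = (rng.uniform(size=(20, 8)) < 0.3).astype(float)
        m = _expr(values)
        ms = _random_modules(rng, m.gene_ids)
        out = filter_nb_supporting_cells(ms, m, min_cells=0, min_frac=0.0)
        assert out.n_modules == ms.n_modules

    def test_matches_bruteforce_double_loop(self, rng):
        values = (rng.uniform(size=(30, 12)) < 0.4).astype(float)
        m = _expr(values)
        ms = _random_modules(rng, m.gene_ids, n_modules=5)
        out = filter_nb_supporting_cells(ms, m, min_cells=3, min_frac=0.5)
        survivors = []
        for genes in ms.gene_lists():
            idx = [m.gene_ids.index(g) for g in genes]
            n_support = 0
            for c in range(12):
                frac = sum(values[i, c] > 0 for i in idx) / len(genes)
                n_support += frac >= 0.5
            if n_support >= 3:
                survivors.append(tuple(genes))
        assert sorted(tuple(g) for g in out.gene_lists()) == sorted(survivors)

    def test_missing_gene_names_module(self):
        m = _expr(np.ones((2, 3)))
        ms = ModuleSet({"M01": ["g0", "absent"]})
        with pytest.raises(ParameterError, match="M01"):
            filter_nb_supporting_cells(ms, m, 1, 0.5)


class TestSdFilter:
    def test_constant_module_removed(self, rng):
        values = np.vstack([np.ones((3, 6)), rng.uniform(0, 5, size=(3, 6))])
        m = _expr(values)
        ms = ModuleSet({"M01": ["g0", "g1", "g2"], "M02": ["g3", "g4", "g5"]})
        out = filter_module_sd(ms, m, 0.1)
        assert out.all_genes() == ["g3", "g4", "g5"]

    def test_zero_threshold_is_identity(self, rng):
        m = _expr(rng.uniform(size=(10, 5)))
        ms = _random_modules(rng, m.gene_ids)
        assert filter_module_sd(ms, m, 0.0).n_modules == ms.n_modules

    def test_statistic_matches_arithmetic_oracle(self, rng):
        from coexmod.filters import module_sd

        values = rng.uniform(0, 3, size=(8, 7))
        m = _expr(values)
        genes = ["g1", "g4", "g6"]
        expected = np.mean(
            [np.std(values[m.gene_ids.index(g)], ddof=1) for g in genes]
        )
        assert module_sd(genes, m) == pytest.approx(expected, abs=1e-12)


class TestFilterAlgebra:
    def test_idempotence_and_commutation(self, rng):
        values = rng.uniform(size=(30, 10))
        values[values < 0.5] = 0.0
        m = _expr(values)
        ms = _random_modules(rng, m.gene_ids, n_modules=6)

        def size3(s):
            return filter_cluster_size(s, 3)

        def support(s):
            return filter_nb_supporting_cells(s, m, 2, 0.4)

        once = support(size3(ms))
        assert support(support(size3(size3(ms)))).modules == once.modules
        assert size3(support(ms)).modules == once.modules


class TestTopGenes:
    def test_small_module_returned_whole(self, rng):
        m = _expr(rng.uniform(size=(5, 6)))
        ms = ModuleSet({"M01": ["g0", "g1"]})
        out = top_genes(ms, m, n_top=20)
        assert sorted(out["M01"]) == ["g0", "g1"]

    def test_anticorrelated_gene_ranks_last(self):
        base = np.linspace(1, 6, 6)
        values = np.vstack([base, base * 1.1 + 0.2, base[::-1]])
        m = _expr(values, gene_ids=["up1", "up2", "down"])
        ms = ModuleSet({"M01": ["up1", "up2", "down"]})
        assert top_genes(ms, m, 3)["M01"][-1] == "down"

    def test_matches_mean_correlation_oracle(self, rng):
        values = rng.uniform(size=(6, 12))
        m = _expr(values)
        genes = list(m.gene_ids)
        ms = ModuleSet({"M01": genes})
        out = top_genes(ms, m, 6)["M01"]
        corr = np.corrcoef(values)
        mean_corr = (corr.sum(axis=1) - 1.0) / (len(genes) - 1)
        expected = [g for _, g in sorted(zip(-mean_corr, genes))]
        assert out == expected


class TestActivityScores:
    def test_perfect_and_absent_recovery(self):
        # cell c0: module genes are the 2 top-ranked; cell c1: module at the bottom
        values = np.array(
            [[9.0, 0.0], [8.0, 0.0], [3.0, 5.0], [2.0, 6.0], [1.0, 7.0], [0.5, 8.0]]
        )
        m = _expr(values)
        ms = ModuleSet({"M01": ["g0", "g1"]})
        scores = module_activity_scores(ms, m, top_fraction=0.5)
        assert scores.loc["M01", "c0"] == pytest.approx(1.0)
        assert scores.loc["M01", "c1"] == pytest.approx(0.0)

    def test_matches_step_curve_integration_oracle(self, rng):
        values = rng.uniform(size=(12, 5))
        m = _expr(values)
        ms = ModuleSet({"M01": ["g0", "g3", "g7"], "M02": ["g1", "g2"]})
        top_fraction = 0.5
        window = int(np.ceil(top_fraction * 12))
        scores = module_activity_scores(ms, m, top_fraction)
        for c, cell in enumerate(m.cell_ids):
            order = sorted(range(12), key=lambda i: (-values[i, c], m.gene_ids[i]))
            for mid, genes in ms.modules.items():
                members = {m.gene_ids.index(g) for g in genes}
                auc = 0
                hits = 0
                for rank in range(window):  # exhaustive recovery curve
                    if order[rank] in members:
                        hits += 1
                    auc += hits
                best = sum(
                    min(len(genes), r + 1) for r in range(window)
                )
                assert scores.loc[mid, cell] == pytest.approx(auc / best)

    def test_duplicated_cell_column_duplicates_scores(self, rng):
        values = rng.uniform(size=(10, 4))
        m = _expr(values)
        m2 = _expr(
            np.hstack([values, values[:, :1]]),
            cell_ids=[f"c{j}" for j in range(4)] + ["c0_copy"],
        )
        ms = _random_modules(rng, m.gene_ids, n_modules=3)
        s1 = module_activity_scores(ms, m, 0.3)
        s2 = module_activity_scores(ms, m2, 0.3)
        np.testing.assert_array_equal(s2["c0_copy"].values, s1["c0"].values)
        assert float(s2.values.min()) >= 0.0 and float(s2.values.max()) <= 1.0
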