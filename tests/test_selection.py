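"""DKNN scoring, null simulation, FDR thresholding and gene selection."""

import numpy as np
import pytest

from coexmod import (
    DistanceMatrix,
    ExpressionMatrix,
    LOGNORM,
    ParameterError,
    SelectionParams,
    compute_dknn,
    estimate_fdr_threshold,
    select_genes,
    simulate_null_dknn,
)
from coexmod.selection import _null_pool

from conftest import make_planted_matrix, random_distance_values


def _dm(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(values.shape[0])]
    return DistanceMatrix(gene_ids, values, "pearson")


def _triangle():
    return _dm([[0, 0.1, 0.5], [0.1, 0, 0.9], [0.5, 0.9, 0]])


class TestComputeDknn:
    def test_nearest_neighbor_readoff(self):
        np.testing.assert_allclose(compute_dknn(_triangle(), 1), [0.1, 0.1, 0.5])

    def test_second_neighbor(self):
        np.testing.assert_allclose(compute_dknn(_triangle(), 2), [0.5, 0.9, 0.9])

    def test_matches_row_sort_oracle(self, rng):
        vals = random_distance_values(rng, 50)
        d = _dm(vals)
        got = compute_dknn(d, 5)
        for i in range(50):
            row = np.sort(np.delete(vals[i], i))  # full-sort oracle
            assert got[i] == row[4]

    @pytest.mark.parametrize("k", [0, 3])
    def test_k_out_of_range(self, k):
        with pytest.raises(ParameterError):
            compute_dknn(_triangle(), k)


class TestNullSimulation:
    def test_constant_pool_gives_constant_dknn(self):
        vals = np.full((6, 6), 0.7)
        np.fill_diagonal(vals, 0.0)
        d = _dm(vals)
        obs = compute_dknn(d, 2)
        sims = simulate_null_dknn(
            d, obs, SelectionParams(k_neighbors=2, n_simulations=100, seed=0)
        )
        assert sims.shape == (100,)
        np.testing.assert_allclose(sims, 0.7)

    def test_noise_level_zero_pools_every_offdiagonal_value(self, rng):
        vals = random_distance_values(rng, 12)
        d = _dm(vals)
        obs = compute_dknn(d, 3)
        pool = _null_pool(d, obs, 0.0)
        assert pool.size == 12 * 11
        mask = ~np.eye(12, dtype=bool)
        np.testing.assert_array_equal(np.sort(pool), np.sort(vals[mask]))

    def test_matches_independent_resampling_oracle(self, rng):
        vals = random_distance_values(rng, 30)
        d = _dm(vals)
        params = SelectionParams(k_neighbors=4, noise_level=0.1, n_simulations=200, seed=9)
        obs = compute_dknn(d, 4)
        sims = simulate_null_dknn(d, obs, params)

        # independently coded resampling with the same documented scheme
        cutoff = np.quantile(obs, 0.1)
        pool = []
        for i in range(30):
            if obs[i] >= cutoff:
                pool.extend([vals[i, j] for j in range(30) if j != i])
        pool = np.array(pool)
        oracle_rng = np.random.default_rng(9)
        oracle = []
        for _ in range(200):
            draw = pool[oracle_rng.choice(pool.size, size=29, replace=False)]
            oracle.append(np.sort(draw)[3])
        assert abs(np.mean(oracle) - np.mean(sims)) < 1e-12

    def test_misaligned_observed_rejected(self, rng):
        vals = random_distance_values(rng, 10)
        d = _dm(vals)
        obs = compute_dknn(d, 2)
        params = SelectionParams(k_neighbors=2, n_simulations=100)
        with pytest.raises(ParameterError):
            simulate_null_dknn(d, obs[:-1], params)


class TestFdrThreshold:
    def test_null_entirely_above_observations(self):
        obs = np.array([0.1, 0.2, 0.3])
        sim = np.array([0.5, 0.6, 0.7, 0.8])
        thr, fdr = estimate_fdr_threshold(obs, sim, 0.05)
        assert thr == 0.3 and fdr == 0.0

    def test_identical_samples_give_no_threshold(self, rng):
        obs = rng.uniform(size=200)
        thr, fdr = estimate_fdr_threshold(obs, obs, 0.05)
        assert thr is None and fdr == 1.0

    def test_exhaustive_candidate_scan_oracle(self):
        obs = np.array([0.1, 0.2, 0.9, 0.95])
        sim = np.array([0.9, 0.92, 0.94, 0.96])
        thr, fdr = estimate_fdr_threshold(obs, sim, 0.25)
        # oracle: scan the four candidates by hand
        best = None
        for t in sorted(obs):
            f = min(1.0, (np.sum(sim <= t) / 4 * 4) / max(1, np.sum(obs <= t)))
            if f <= 0.25:
                best = (t, f) if best is None or t > best[0] else best
        assert best == (0.2, 0.0)
        assert (thr, fdr) == best

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -1.0])
    def test_alpha_domain(self, alpha):
        with pytest.raises(ParameterError):
            estimate_fdr_threshold(np.array([1.0]), np.array([1.0]), alpha)


class TestSelectGenes:
    def test_planted_module_recovered(self, planted_one_block):
        m, blocks = planted_one_block
        params = SelectionParams(
            k_neighbors=10, fdr_target=1e-3, n_simulations=500, seed=3, row_sum=0
        )
        res = select_genes(m, params)
        selected = set(res.selected_genes)
        assert set(blocks[0]) <= selected
        noise = [g for g in res.gene_ids if g.startswith("noise")]
        rejected = sum(g not in selected for g in noise)
        assert rejected / len(noise) >= 0.95

    def test_homogeneous_noise_is_calibrated(self):
        rng = np.random.default_rng(5)
        values = np.abs(rng.normal(1.0, 1.0, size=(500, 80)))
        m = ExpressionMatrix(
            [f"g{i:03d}" for i in range(500)],
            [f"c{j}" for j in range(80)],
            values,
            LOGNORM,
        )
        res = select_genes(
            m, SelectionParams(k_neighbors=10, fdr_target=1e-3, n_simulations=500, seed=5, row_sum=0)
        )
        assert len(res.selected_genes) / len(res.gene_ids) <= 0.01

    def test_row_sum_prefilter_exact(self, rng):
        values = np.zeros((6, 10))
        for i in range(6):
            values[i, : i + 2] = rng.uniform(1, 2, size=i + 2)  # gene i in i+2 cells
        m = ExpressionMatrix(
            [f"g{i}" for i in range(6)], [f"c{j}" for j in range(10)], values, LOGNORM
        )
        params = SelectionParams(k_neighbors=1, row_sum=5, n_simulations=100, seed=0)
        res = select_genes(m, params)
        assert res.dropped_low_rowsum == ["g0", "g1", "g2"]
        assert res.gene_ids == ["g3", "g4", "g5"]

    def test_lower_alpha_never_enlarges_selection(self, planted_one_block):
        m, _ = planted_one_block
        common = dict(k_neighbors=10, n_simulations=300, seed=3, row_sum=0)
        sel_loose = select_genes(m, SelectionParams(fdr_target=0.05, **common))
        sel_tight = select_genes(m, SelectionParams(fdr_target=1e-4, **common))
        assert set(sel_tight.selected_genes) <= set(sel_loose.selected_genes)

    def test_duplicated_gene_row_gets_dknn_zero(self, planted_one_block):
        # at K=1 a duplicated row makes both copies each other's nearest
        # neighbor at correlation distance exactly 0
        m, _ = planted_one_block
        values = np.vstack([m.dense(), m.dense()[:1]])
        dup = ExpressionMatrix(m.gene_ids + ["dup_of_first"], m.cell_ids, values, LOGNORM)
        res = select_genes(
            dup, SelectionParams(k_neighbors=1, fdr_target=1e-3, n_simulations=300, seed=3, row_sum=0)
        )
        idx = {g: i for i, g in enumerate(res.gene_ids)}
        assert res.observed_dknn[idx[m.gene_ids[0]]] == pytest.approx(0.0, abs=1e-12)
        assert res.observed_dknn[idx["dup_of_first"]] == pytest.approx(0.0, abs=1e-12)
        if res.threshold is not None and res.threshold > 0:
            assert {m.gene_ids[0], "dup_of_first"} <= set(res.selected_genes)

    def test_same_seed_identical_result(self, planted_one_block):
        m, _ = planted_one_block
        params = SelectionParams(k_neighbors=10, n_simulations=200, seed=8, row_sum=0)
        a = select_genes(m, params)
        b = select_genes(m, params)
        assert a.gene_ids == b.gene_ids
        np.testing.assert_array_equal(a.observed_dknn, b.observed_dknn)
        np.testing.assert_array_equal(a.simulated_dknn, b.simulated_dknn)
        assert a.threshold == b.threshold and a.selected_genes == b.selected_genes

    def test_selection_semantics_match_threshold(self, planted_one_block):
        m, _ = planted_one_block
        res = select_genes(
            m, SelectionParams(k_neighbors=10, fdr_target=1e-3, n_simulations=300, seed=3, row_sum=0)
        )
        assert res.threshold is not None
        expected = {g for g, v in zip(res.gene_ids, res.observed_dknn) if v <= res.threshold}
        assert set(res.selected_genes) == expected

    def test_too_few_genes_for_k(self):
        rng = np.random.default_rng(0)
        values = np.abs(rng.normal(1, 1, size=(5, 10)))
        m = ExpressionMatrix(
            [f"g{i}" for i in range(5)], [f"c{j}" for j in range(10)], values, LOGNORM
        )
        with pytest.raises(ParameterError):
            select_genes(m, SelectionParams(k_neighbors=10, n_simulations=100, row_sum=0))


class TestSelectionParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fdr_target": 0.0},
            {"fdr_target": 1.0},
            {"noise_level": 1.0},
            {"noise_level": -0.1},
            {"n_simulations": 10},
            {"k_neighbors": 0},
            {"metric": "manhattan"},
        ],
    )
    def test_domain_validation(self, kwargs):
        with pytest.raises(ParameterError):
            SelectionParams(**kwargs)
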