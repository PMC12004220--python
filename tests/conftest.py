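"""Shared fixtures: small deterministic matrices and planted-signal data."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from coexmod import LOGNORM, RAW_COUNTS, ExpressionMatrix

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_counts(rng) -> ExpressionMatrix:
    """10 genes x 6 cells of Poisson counts, no structure."""
    values = rng.poisson(3.0, size=(10, 6)).astype(float)
    values[0, :] += 1  # keep every cell total positive
    return ExpressionMatrix(
        [f"g{i}" for i in range(10)], [f"c{j}" for j in range(6)], values, RAW_COUNTS
    )


def make_planted_matrix(
    n_module: int = 40,
    n_noise: int = 400,
    n_cells: int = 60,
    n_blocks: int = 1,
    signal_sd: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 7,
) -> tuple[ExpressionMatrix, list[list[str]]]:
    """Non-negative matrix with ``n_blocks`` planted co-expressed blocks.

    Block genes share a latent cell profile plus independent noise; the
    remaining genes are pure iid noise. Returns the matrix (lognorm layer)
    and the planted gene lists.
    """
    rng = np.random.default_rng(seed)
    rows = []
    gene_ids = []
    blocks: list[list[str]] = []
    for b in range(n_blocks):
        latent = rng.uniform(0.0, 4.0, size=n_cells)
        names = [f"mod{b}_{i:03d}" for i in range(n_module)]
        blocks.append(names)
        gene_ids.extend(names)
        for _ in range(n_module):
            rows.append(signal_sd * latent + np.abs(rng.normal(0, noise_sd, n_cells)))
    for i in range(n_noise):
        gene_ids.append(f"noise_{i:04d}")
        rows.append(np.abs(rng.normal(0, 1.0, n_cells)))
    values = np.asarray(rows)
    cell_ids = [f"c{j:03d}" for j in range(n_cells)]
    return ExpressionMatrix(gene_ids, cell_ids, values, LOGNORM), blocks


@pytest.fixture()
def planted_one_block():
    return make_planted_matrix(n_module=40, n_noise=400, n_cells=60, seed=7)


@pytest.fixture()
def planted_two_blocks():
    return make_planted_matrix(
        n_module=30, n_noise=120, n_cells=80, n_blocks=2, seed=11
    )


def random_distance_values(rng, n: int) -> np.ndarray:
    """A valid random distance matrix (symmetric, zero diagonal)."""
    d = rng.uniform(0.01, 2.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d
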