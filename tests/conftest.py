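"""Shared fixtures: small synthetic references sized for fast tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pitdeconv import SimConfig, generate_reference
from pitdeconv.prep import SignatureMatrix


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Four endocrine types, tiny transcriptome; generation takes < 1 s."""
    return SimConfig(
        cell_types=("somatotroph", "lactotroph", "gonadotroph", "corticotroph"),
        n_genes=400,
        markers_per_type=40,
        cells_per_type=60,
        n_subjects=2,
        marker_fold=8.0,
        libsize_mean=3000.0,
        n_mito_genes=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def ortho_signature() -> SignatureMatrix:
    """Three mutually exclusive marker-block profiles (50 genes per block,
    log-normal marker levels around ~2000 CPM on a flat 5 CPM background)."""
    rng = np.random.default_rng(2024)
    n_per, k = 50, 3
    genes = [f"G{i:03d}" for i in range(n_per * k)]
    vals = np.full((n_per * k, k), 5.0)
    for j in range(k):
        vals[j * n_per : (j + 1) * n_per, j] = rng.lognormal(7.5, 0.8, n_per)
    values = pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=["A", "B", "C"])
    return SignatureMatrix(
        values=values,
        members={t: genes[j * n_per : (j + 1) * n_per] for j, t in enumerate("ABC")},
        name="ortho",
    )


def simplex_grid_oracle(S: np.ndarray, y: np.ndarray, step: float = 0.01) -> np.ndarray:
    """Brute-force reconstruction-RMSE minimizer over the probability simplex.

    Enumerates all compositions on a regular grid (step 0.01 by default) and
    returns the one minimizing ||S w - y||. Independent of both engines; only
    2- and 3-type signatures are practical.
    """
    k = S.shape[1]
    ticks = int(round(1.0 / step))
    best_w, best_err = None, np.inf
    if k == 2:
        combos = ((i, ticks - i) for i in range(ticks + 1))
    elif k == 3:
        combos = (
            (i, j, ticks - i - j)
            for i in range(ticks + 1)
            for j in range(ticks + 1 - i)
        )
    else:
        raise ValueError("oracle supports 2 or 3 components only")
    for combo in combos:
        w = np.array(combo, dtype=float) / ticks
        err = float(np.linalg.norm(S @ w - y))
        if err < best_err:
            best_err, best_w = err, w
    return best_w
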