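import numpy as np
import pytest

from stemsvm.features import build_chip_matrices, normalize_expression_matrix
from stemsvm.layout import default_layout
from stemsvm.synthetic import (
    SimulationConfig,
    generate_universe,
    simulate_chip_peaks,
    simulate_expression,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_pos=12, n_neg=16, n_unlabeled=60, effect_size=2.5, noise_sd=0.5, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Genes, labels, and the three feature blocks for a small simulation."""
    genes = generate_universe(small_config)
    expr = simulate_expression(genes, default_layout(), small_config)
    peaks = simulate_chip_peaks(genes, small_config)
    Xm_df = normalize_expression_matrix(expr)
    Xb_df, Xc_df = build_chip_matrices(genes, peaks)
    labeled = [g for g in genes if g.label != "unlabeled"]
    ids = [g.gene_id for g in labeled]
    y = np.array([1 if g.label == "positive" else -1 for g in labeled])
    return {
        "genes": genes,
        "labeled_ids": ids,
        "y": y,
        "expr": expr,
        "peaks": peaks,
        "Xm": Xm_df.loc[ids].to_numpy(),
        "Xb": Xb_df.loc[ids].to_numpy(),
        "Xc": Xc_df.loc[ids].to_numpy(),
        "Xm_df": Xm_df,
        "Xb_df": Xb_df,
        "Xc_df": Xc_df,
    }


@pytest.fixture
def separable_xy():
    """Wide-margin linearly separable 2-feature toy data."""
    rng = np.random.default_rng(0)
    n = 10
    X_pos = rng.normal([3.0, 3.0], 0.2, size=(n, 2))
    X_neg = rng.normal([-3.0, -3.0], 0.2, size=(n, 2))
    X = np.vstack([X_pos, X_neg])
    y = np.array([1] * n + [-1] * n)
    return X, y
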