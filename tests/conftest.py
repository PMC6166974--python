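import numpy as np
import pandas as pd
import pytest

import te_regnet as tr


@pytest.fixture(scope="session")
def small_bundle():
    """A small planted-effect bundle shared by read-only tests."""
    cfg = tr.SimulationConfig(seed=11, n_genes=800, n_tissues=4,
                              te_fraction=0.1, effect_size=2.0)
    return tr.simulate_bundle(cfg)


@pytest.fixture()
def toy_expression():
    """Deterministic 6-gene, 2-tissue, 2-samples-per-tissue TPM matrix."""
    rng = np.random.default_rng(42)
    values = rng.lognormal(3.0, 1.0, size=(6, 4))
    values = values / values.sum(axis=0) * 1e6
    samples = ["pla_1", "pla_2", "liv_1", "liv_2"]
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(6)], columns=samples)
    tissue = pd.Series({"pla_1": "placenta", "pla_2": "placenta",
                        "liv_1": "liver", "liv_2": "liver"})
    return tr.ExpressionMatrix(df, tissue)


def make_expression(n_genes, tissues, n_samples, seed, planted=None, shift=0.0):
    """Log-normal TPM matrix with an optional up-shift of `planted` genes
    in the first tissue."""
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    cols, tissue_of = {}, {}
    base = rng.normal(4.0, 1.0, n_genes)
    for t in tissues:
        for j in range(n_samples):
            s = f"{t}_s{j}"
            x = base + rng.normal(0.0, 0.5, n_genes)
            if planted is not None and t == tissues[0]:
                x = x + shift * np.isin(np.arange(n_genes), planted)
            cols[s] = np.exp(x)
            tissue_of[s] = t
    df = pd.DataFrame(cols, index=gene_ids)
    df = df / df.sum(axis=0) * 1e6
    return tr.ExpressionMatrix(df, pd.Series(tissue_of))
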