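import numpy as np
import pandas as pd
import pytest

import dupli_td as dt
from dupli_td.simulate import default_design


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared by read-only tests."""
    cfg = dt.SimConfig(
        n_singletons=200, n_wgd_pairs=60, n_ssd_pairs=60, frac_de=0.3,
        de_lfc_sd=1.5, seed=42,
    )
    catalog, truth = dt.simulate_catalog(cfg)
    design = default_design(cfg.n_replicates, timepoints=("t0",))
    counts = dt.simulate_counts(catalog, truth, cfg, design)
    return cfg, catalog, truth, design, counts


@pytest.fixture(scope="session")
def small_de(small_sim):
    cfg, catalog, truth, design, counts = small_sim
    model = dt.NBExpressionModel(dt.CountMatrix(counts, design))
    return model.fit("t0")


def two_group_counts(n_genes, mu, lfc, phi, n_rep, seed, de_mask=None):
    """Direct NB two-group count matrix without the catalog machinery."""
    rng = np.random.default_rng(seed)
    mu = np.full(n_genes, float(mu)) if np.isscalar(mu) else np.asarray(mu, float)
    lfc_vec = np.zeros(n_genes)
    if de_mask is not None:
        lfc_vec[de_mask] = lfc
    mu_e = mu * 2.0**lfc_vec

    def draw(m):
        lam = rng.gamma(1.0 / phi, phi * m[:, None] * np.ones((1, n_rep)))
        return rng.poisson(lam)

    counts = pd.DataFrame(
        np.hstack([draw(mu), draw(mu_e)]),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"d{i}" for i in range(n_rep)] + [f"e{i}" for i in range(n_rep)],
    )
    design = pd.DataFrame(
        {
            "sample": counts.columns,
            "line": "x",
            "timepoint": "t0",
            "medium": ["YPD"] * n_rep + ["YPE"] * n_rep,
            "replicate": list(range(1, n_rep + 1)) * 2,
        }
    )
    return counts, design
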