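import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import crcprograms as c

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 patients x 50 cells, 400 genes, planted programs of 50 genes."""
    cfg = c.default_spheroid_config(
        seed=7, n_patients=3, cells_per_patient=50, n_genes=400, program_size=50
    )
    return c.generate_spheroid_cohort(cfg), cfg


@pytest.fixture()
def expression_matrix():
    """Deterministic small expression AnnData (values are E, not counts)."""
    rng = np.random.default_rng(42)
    X = rng.uniform(0.0, 8.0, size=(30, 50))
    obs = pd.DataFrame(
        {"patient": ["A"] * 15 + ["B"] * 15},
        index=[f"c{i:02d}" for i in range(30)],
    )
    var = pd.DataFrame(index=[f"g{i:03d}" for i in range(50)])
    return ad.AnnData(X=X, obs=obs, var=var)


def make_counts(counts, patients=None, reads=None, mito=None):
    """Build a minimal counts AnnData from a dense array (cells x genes)."""
    counts = np.asarray(counts)
    n, g = counts.shape
    obs = pd.DataFrame(
        {
            "patient": patients if patients is not None else ["P1"] * n,
            "total_reads": reads if reads is not None else [200_000] * n,
            "mito_fraction": mito if mito is not None else [0.05] * n,
        },
        index=[f"c{i:03d}" for i in range(n)],
    )
    var = pd.DataFrame(index=[f"g{i:03d}" for i in range(g)])
    return ad.AnnData(X=counts.astype(np.int64), obs=obs, var=var)
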