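import numpy as np
import pandas as pd
import pytest

from poolassoc.simulate import MAFSpec, SimConfig, simulate_pool_experiment


@pytest.fixture(scope="session")
def small_null_experiment():
    """A compact null experiment (no causal sites, no bias) reused across tests."""
    cfg = SimConfig(
        n_case_pools=6,
        n_control_pools=6,
        pool_sizes=(24,),
        n_batches=3,
        n_sites=200,
        maf_distribution=MAFSpec("uniform", low=0.05, high=0.5),
        mean_depth=800,
        seed=2024,
    )
    matrix, manifest, truth = simulate_pool_experiment(cfg)
    return cfg, matrix, manifest, truth


@pytest.fixture()
def toy_manifest():
    return pd.DataFrame(
        {
            "pool_id": ["p1", "p2", "p3", "p4", "p5", "p6"],
            "status": ["case", "case", "case", "control", "control", "control"],
            "n_individuals": [24, 24, 12, 24, 24, 12],
            "batch": ["A", "A", "B", "A", "B", "B"],
        }
    )


def make_matrix(rows):
    """Build a site call matrix from (chrom,pos,ref,allele,pool,fwd,rev) tuples."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "allele", "pool_id", "fwd", "rev"]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
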