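import numpy as np
import pytest

from cutrun.synthetic import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """A 400-kb two-dataset synthetic run shared by read-only tests."""
    cfg = SimConfig(
        seed=11,
        chrom_sizes={"chr1": 200_000, "chr2": 200_000},
        n_rss12=5,
        n_rss23=5,
        n_junctions=60,
        rss_proximal_fraction=0.3,
        n_patient_bps=24,
        n_planted_overlaps=6,
    )
    return simulate_all(
        cfg,
        datasets=[("sj", 60, 0.3), ("control", 60, 0.05)],
        repertoire=dict(
            n_v=12, n_j=4, consensus_pair_fraction=0.6, usage_model="dirichlet"
        ),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
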