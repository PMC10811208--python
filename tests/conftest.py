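import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import admixscan as ax

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_gm(G, depths=None, chrom="chr1", spacing=1000, sample_prefix="s",
            chrom_lengths=None):
    """Small genotype matrix with evenly spaced loci (testing helper)."""
    G = np.asarray(G, dtype=np.int8)
    n, m = G.shape
    loci = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * spacing,
            "ref": "A",
            "alt": "C",
        }
    )
    return ax.GenotypeMatrix(
        [f"{sample_prefix}{i}" for i in range(n)], loci, G,
        D=None if depths is None else np.asarray(depths),
        chrom_lengths=chrom_lengths,
    )


def random_gm(rng, n=20, m=50, miss_rate=0.1, with_depth=False):
    G = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    G[rng.random((n, m)) < miss_rate] = -1
    D = rng.poisson(8, size=(n, m)) if with_depth else None
    return make_gm(G, depths=D)


@pytest.fixture(scope="session")
def ancestry_study():
    """Two-ancestry crossbred study at F = 0.2, G = 10: reference panels of
    50, an admixed cohort of 60 with mean ancestry-2 proportion 0.6278, and
    5,000 loci on five 20-Mb chromosomes (shared across tests)."""
    cfg = ax.SimulationConfig(
        n_loci=5000,
        chrom_lengths={f"chr{i}": 20_000_000 for i in range(1, 6)},
        n_panel1=50, n_panel2=50, n_admixed=60, n_admixed2=10,
        fst_divergence=0.2, gen_since_admix=10.0,
        miss_rate_slaf=0.1, miss_rate_wgs=0.02,
        seed=2024,
    )
    return ax.simulate_study(cfg)


@pytest.fixture(scope="session")
def diverged_pair_study():
    """Two strongly diverged panels (F = 0.3) for structure tests."""
    cfg = ax.SimulationConfig(
        n_loci=1000, chrom_lengths={"chr1": 5_000_000},
        n_panel1=4, n_panel2=4, n_admixed=2, n_admixed2=2,
        fst_divergence=0.3, miss_rate_slaf=0.0, miss_rate_wgs=0.0,
        seed=7,
    )
    return ax.simulate_study(cfg)
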