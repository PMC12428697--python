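import numpy as np
import pandas as pd
import pytest

from panpav import simdata
from panpav.containers import VariantPanel


@pytest.fixture(scope="session")
def small_pav_config():
    """A reduced gene complement for fast unit tests (same band structure)."""
    return simdata.SimPavConfig(
        n_samples=30,
        n_genes_per_class={"core": 40, "softcore": 0, "shell": 30, "cloud": 0},
        seed=42,
    )


@pytest.fixture(scope="session")
def small_pav(small_pav_config):
    pav, truth = simdata.sim_pav(small_pav_config)
    return pav, truth


@pytest.fixture(scope="session")
def two_pop_panel():
    """A small two-population drift panel shared by popgen/structure tests."""
    cfg = simdata.SimPopConfig(
        n_pops=2, samples_per_pop=(15, 15), n_sites=3000,
        drift=0.2, chrom_length=2_000_000, seed=7,
    )
    return simdata.sim_genotypes(cfg)


def make_panel(genotypes, pops=None, quals=None, alts=None):
    """Hand-build a VariantPanel from a (sites x samples) dosage array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    samples = [f"s{i}" for i in range(n_samples)]
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_sites + 1) * 10,
            "ref": "A",
            "alt": alts if alts is not None else ["C"] * n_sites,
            "qual": quals if quals is not None else [50.0] * n_sites,
        }
    )
    popmap = dict(zip(samples, pops)) if pops is not None else {}
    return VariantPanel(sites, g, samples, popmap)
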