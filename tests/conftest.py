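import numpy as np
import pandas as pd
import pytest

from drophic import SimConfig, cpg_density, make_bins, sim_genome


def contacts_frame(rows):
    """Build a contacts DataFrame from (barcode, c1, p1, c2, p2[, q1, q2]) tuples."""
    full = [r if len(r) == 7 else (*r, 60, 60) for r in rows]
    return pd.DataFrame(
        full, columns=["barcode", "chrom1", "pos1", "chrom2", "pos2", "mapq1", "mapq2"]
    )


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale simulator config shared across tests."""
    return SimConfig(
        seed=101, n_cells=12, n_ambient=200, contacts_mean=3000,
        ambient_mean=10,
    )


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return sim_genome(small_cfg)


@pytest.fixture(scope="session")
def small_cpg(small_genome):
    return cpg_density(small_genome.sequences, small_genome.bins)


@pytest.fixture
def toy_bins():
    return make_bins({"chrA": 100_000, "chrB": 50_000}, 10_000)
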