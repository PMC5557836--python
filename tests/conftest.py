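import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from applepop.io_formats import GenotypeDataset, PopulationGrouping
from applepop import synthetic_data as sd


def make_dataset(dosages, positions=None, chrom="chr1", accessions=None):
    """Small helper: build a GenotypeDataset from a (acc x site) list."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_acc, n_sites = dosages.shape
    if positions is None:
        positions = list(range(100, 100 + 10 * n_sites, 10))
    if accessions is None:
        accessions = [f"acc{i + 1}" for i in range(n_acc)]
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "C"}
    )
    return GenotypeDataset(accessions, sites, dosages)


@pytest.fixture(scope="session")
def two_pop_sim():
    """Two drifted populations, no admixture — shared across statistic tests."""
    cfg = sd.SimulationConfig(
        seed=11,
        chromosomes=[("chr1", 1_000_000)],
        populations=[
            sd.PopulationSpec("P1", 20, 0.1),
            sd.PopulationSpec("P2", 20, 0.1),
        ],
        snp_density=0.002,
    )
    return sd.simulate(cfg)


@pytest.fixture(scope="session")
def mosaic_sim():
    """Admixed mosaic with two deeply diverged wild sources (session-scoped:
    the ancestry tests all read from it)."""
    chroms = [(f"chr{i + 1}", 2_000_000) for i in range(5)]
    cfg = sd.SimulationConfig(
        seed=23,
        chromosomes=chroms,
        populations=[
            sd.PopulationSpec("Sie_K", 40, 0.7, 0.1),
            sd.PopulationSpec("Syl", 40, 0.7, 0.1),
        ],
        admixed=sd.AdmixedSpec(
            "Dom", 40, 100_000, {"Sie_K": 0.5, "Syl": 0.3, None: 0.2}
        ),
    )
    return sd.simulate(cfg), dict(chroms)
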