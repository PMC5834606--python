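import numpy as np
import pandas as pd
import pytest

from fusionscan import SimConfig, simulate_fusion_dataset
from fusionscan.popio import GenotypeMatrix


@pytest.fixture(scope="session")
def fusion_sim():
    """Moderate fusion-mode dataset: 5 transect pops + CHI, narrow cline."""
    cfg = SimConfig(
        n_loci=1500, n_pops=5, samples_per_pop=20, seed=42,
        cline_width_km=400.0, missing_rate=0.02,
    )
    return cfg, simulate_fusion_dataset(cfg)


@pytest.fixture(scope="session")
def pop_samples(fusion_sim):
    _, sim = fusion_sim
    return sim.metadata.groupby("population")["sample"].apply(list).to_dict()


def tiny_matrix(dosage, ploidy=None, z_linked=None, samples=None):
    """Hand-built GenotypeMatrix from a small dosage array."""
    dosage = np.asarray(dosage, dtype=np.int16)
    n, m = dosage.shape
    if ploidy is None:
        ploidy = np.full((n, m), 2, dtype=np.int8)
    z = np.zeros(m, dtype=bool) if z_linked is None else np.asarray(z_linked)
    loci = pd.DataFrame(
        {
            "chrom": ["scaf_1"] * m,
            "pos": np.arange(1, m + 1) * 100,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "z_linked": z,
        }
    )
    return GenotypeMatrix(
        samples=samples or [f"s{i}" for i in range(n)],
        loci=loci,
        dosage=dosage,
        ploidy=np.asarray(ploidy, dtype=np.int8),
    )
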