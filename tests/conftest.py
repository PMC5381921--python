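import numpy as np
import pandas as pd
import pytest

from rhmap.genio import GenotypeMatrix
from rhmap.syndata import SimConfig, simulate_dataset


def make_genotypes(values, chrom=None, ids=None):
    """Small helper: wrap a raw array in a GenotypeMatrix with a trivial map."""
    values = np.asarray(values, float)
    n, m = values.shape
    chrom = chrom if chrom is not None else np.ones(m, int)
    snp_map = pd.DataFrame(
        {
            "name": [f"s{i}" for i in range(m)],
            "chrom": chrom,
            "bp": np.arange(1, m + 1) * 1000,
        }
    )
    ids = ids or [f"i{j}" for j in range(n)]
    return GenotypeMatrix(values=values, snp_map=snp_map, ids=ids)


@pytest.fixture(scope="session")
def small_dataset():
    """One shared 300-individual, 400-SNP dataset with a 20-SNP regional QTL."""
    cfg = SimConfig(
        n_individuals=300,
        chromosome_snp_counts=(200, 200),
        trait_names=("Y",),
        whole_var=(400.0,),
        resid_var=(400.0,),
        regional_window=(1, 40, 20),
        regional_var=(160.0,),
        seed=11,
    )
    gm, pheno, truth = simulate_dataset(cfg)
    return cfg, gm, pheno, truth
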