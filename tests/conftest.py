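import numpy as np
import pandas as pd
import pytest

from smrkit.refpanel import ReferencePanel
from smrkit.simulate import SyntheticScenario, simulate_study


def make_panel(genotypes, snp_ids=None, alleles=None, chrom="1", pos0=100):
    """Construct a small in-memory panel from a dosage matrix."""
    genotypes = np.asarray(genotypes, dtype=float)
    n_ind, n_var = genotypes.shape
    snp_ids = snp_ids or [f"rs{i + 1}" for i in range(n_var)]
    alleles = alleles or [("A", "G")] * n_var
    variants = pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom,
        "pos": pos0 + np.arange(n_var),
        "a1": [a for a, _ in alleles], "a2": [b for _, b in alleles],
    })
    iids = [f"i{k}" for k in range(n_ind)]
    return ReferencePanel(variants=variants, genotypes=genotypes,
                          individual_ids=iids)


@pytest.fixture(scope="session")
def pleiotropy_study():
    """One seeded pleiotropy realization shared across read-only tests."""
    return simulate_study(SyntheticScenario(architecture="pleiotropy", seed=42))
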