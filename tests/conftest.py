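"""Shared fixtures: small synthetic cohorts with known ground truth."""

import numpy as np
import pytest

from permforge import GenotypeMatrix, SimSpec, adjust_phenotype, \
    simulate_genotypes, simulate_phenotype


@pytest.fixture(scope="session")
def small_cohort():
    """100 SNPs x 50 samples with 5% missingness and a null phenotype."""
    spec = SimSpec(m=100, n=50, missing_rate=0.05, seed=11)
    G, mafs = simulate_genotypes(spec)
    b, _ = simulate_phenotype(G, spec)
    return G, mafs, b


@pytest.fixture(scope="session")
def tiny_dataset():
    """Deterministic 4 SNPs x 7 samples, no missing data, exact integer y.

    Small enough for exhaustive enumeration of all 5040 phenotype
    permutations.
    """
    rng = np.random.Generator(np.random.PCG64(2024))
    codes = rng.integers(0, 3, size=(4, 7)).astype(np.int8)
    # ensure every row is polymorphic
    codes[:, 0] = 0
    codes[:, 1] = 2
    G = GenotypeMatrix(codes)
    y = np.array([-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0])  # zero-sum, exact
    from permforge.model import PhenotypeSet
    pheno = PhenotypeSet(b_raw=y, C=None, y=y, ss_y=float(y @ y))
    return G, pheno


@pytest.fixture()
def null_pheno(small_cohort):
    G, _, b = small_cohort
    return adjust_phenotype(b)
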