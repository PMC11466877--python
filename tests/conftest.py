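import numpy as np
import pandas as pd
import pytest

from soyshade.datatypes import GenotypeMatrix, PhenotypeTable
from soyshade.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small but structured panel: 40 accessions, 200 SNPs, 4 replicates."""
    return SimulationConfig(
        n_accessions=40,
        n_chrom=4,
        chrom_length_bp=2_000_000,
        n_snps=200,
        n_replicates=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_genotypes(small_config) -> GenotypeMatrix:
    return simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def small_phenotypes(small_config, small_genotypes) -> PhenotypeTable:
    return simulate_phenotypes(small_genotypes, small_config)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return simulate_annotation(small_config)


@pytest.fixture()
def tiny_genotypes() -> GenotypeMatrix:
    """Hand-written 3 accessions x 2 SNPs for exact-value tests."""
    snps = pd.DataFrame(
        {
            "snp_id": ["S1_100", "S2_500"],
            "chrom": [1, 2],
            "pos": [100, 500],
            "ref": ["A", "C"],
            "alt": ["G", "T"],
        }
    )
    dosage = np.array([[0, 2], [1, 1], [2, 0]], dtype=np.int8)
    return GenotypeMatrix(["acc1", "acc2", "acc3"], snps, dosage)
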