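import numpy as np
import pytest

from kindredscope.datasets import load_gene_panel, load_kindred
from kindredscope.segregation import GenotypeTable
from kindredscope.simulate import SimConfig, simulate_panel, simulate_sequences


@pytest.fixture(scope="session")
def kindred1():
    """Worked-example kindred 1: (variants, pedigree, genotype table)."""
    return load_kindred("kindred1")


@pytest.fixture(scope="session")
def kindred2():
    return load_kindred("kindred2")


@pytest.fixture(scope="session")
def gene_panel():
    return load_gene_panel()


@pytest.fixture()
def kindred1_exome_table(kindred1):
    """Kindred-1 genotype table without the structural-deletion column."""
    _, _, table = kindred1
    mask = table.variants["variant_id"] != "LDLR:exon1del"
    calls = {k: v for k, v in table.calls.items() if k != "LDLR:exon1del"}
    return GenotypeTable(table.variants[mask], calls)


@pytest.fixture(scope="session")
def small_panel():
    """Six-population Balding-Nichols panel used across ancestry tests."""
    cfg = SimConfig(seed=11, n_populations=6, n_snps=300, n_per_population=50, fst=0.05)
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def allele_pair():
    """Synthetic wild-type / deleted allele pair with default assay geometry."""
    return simulate_sequences(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
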