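import numpy as np
import pandas as pd
import pytest

from szprior import (
    SyntheticConfig,
    gen_association_data,
    gen_evidence,
    gen_gene_universe,
    gen_gwas_universe,
)


@pytest.fixture(scope="session")
def cfg():
    """Small, fast study design shared across tests (null: no planted signal)."""
    return SyntheticConfig(
        n_genes=120,
        n_linkage_regions=6,
        genome_length=120_000_000,
        ppi_n_edges=600,
        mean_snps_per_gene=8.0,
        gwas_n_genes=250,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def signal_cfg():
    """Design with planted signal concentrated in the neurodev label."""
    return SyntheticConfig(
        n_genes=120,
        n_linkage_regions=6,
        genome_length=120_000_000,
        ppi_n_edges=600,
        mean_snps_per_gene=8.0,
        gwas_n_genes=250,
        frac_neurodev=0.3,
        frac_associated_genes=0.3,
        associate_neurodev=True,
        effect_size=1.5,
        n_trios=500,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def universe(cfg):
    return gen_gene_universe(cfg)


@pytest.fixture(scope="session")
def genes(universe):
    return universe[0]


@pytest.fixture(scope="session")
def evidence_inputs(genes, cfg):
    return gen_evidence(genes, cfg)


@pytest.fixture(scope="session")
def snp_results(genes, cfg):
    return gen_association_data(genes, cfg)


@pytest.fixture(scope="session")
def gwas(cfg):
    return gen_gwas_universe(cfg)
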