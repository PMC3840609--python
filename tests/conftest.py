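import dataclasses

import numpy as np
import pytest

import growthnet as gn


@pytest.fixture(scope="session")
def tiny_config():
    """A small no-module F2 cross for structural tests."""
    return dataclasses.replace(
        gn.default_config(seed=7, with_modules=False),
        n_founders_per_breed=4,
        n_f1=10,
        n_f2=60,
        n_chromosomes=2,
        snps_per_chromosome=30,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return gn.simulate_dataset(tiny_config)


@pytest.fixture(scope="session")
def default_scenario():
    """The planted-module desk-scale scenario, run through the pipeline once."""
    cfg = gn.default_config(seed=1)
    ped, snp_map, genes, geno, traits, truth = gn.simulate_dataset(cfg)
    gwas = gn.run_gwas(gn.qc_filter(geno), traits, ped)
    awm = gn.build_awm(gwas, snp_map, genes, traits.key_traits, traits.supportive_traits)
    net, r, sig = gn.network_from_awm(awm)
    return {
        "config": cfg,
        "pedigree": ped,
        "snp_map": snp_map,
        "genes": genes,
        "genotypes": geno,
        "traits": traits,
        "truth": truth,
        "gwas": gwas,
        "awm": awm,
        "network": net,
        "r": r,
        "sig": sig,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
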