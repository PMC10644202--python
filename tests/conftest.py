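"""Shared fixtures: small simulated studies generated at test time."""

import numpy as np
import pytest

from gstrial import sim


@pytest.fixture(scope="session")
def tiny_config():
    """A desk-scale trial: 24 families x 3/block x 2 blocks, 375 SNPs."""
    return sim.SimConfig(
        n_mothers=24,
        progeny_per_family_per_block=3,
        n_blocks=2,
        n_founder_haplotypes=100,
        n_scaffolds=15,
        snps_per_scaffold=25,
        scaffold_length_bp=25_000,
        ld_decay_bp=2000.0,
        n_qtl_additive=30,
        n_qtl_epistatic_pairs=20,
        h2_additive=0.35,
        h2_epistatic=0.0,
        spatial_variance_fraction=0.15,
        phenotype_missing_rate=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    """(phase, codes, pedigree, phenotypes, panel, architectures)."""
    return sim.simulate_study(tiny_config)


@pytest.fixture(scope="session")
def additive_population():
    """A larger purely additive population for recovery checks:
    n=280 genotyped trees, ~600 SNPs, planted h2 = 0.35."""
    cfg = sim.SimConfig(
        n_mothers=35,
        progeny_per_family_per_block=4,
        n_blocks=2,
        n_founder_haplotypes=140,
        n_scaffolds=30,
        snps_per_scaffold=20,
        scaffold_length_bp=20_000,
        n_qtl_additive=60,
        h2_additive=0.35,
        h2_epistatic=0.0,
        spatial_variance_fraction=0.0,
        phenotype_missing_rate=0.0,
        seed=29,
    )
    panel = sim.simulate_founder_haplotypes(cfg)
    phase, ped = sim.simulate_progeny(panel, cfg)
    codes = sim.codes_from_phase(phase).astype(float)
    arch, genetic = sim.simulate_trait(sim.codes_from_phase(phase), cfg)
    rng = np.random.default_rng(5)
    y = genetic + rng.normal(0, arch.residual_sd, len(genetic))
    return cfg, codes, y, genetic, arch
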