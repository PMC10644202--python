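"""Progeny-trial simulator: design counts, Mendelian consistency, LD and
variance-fraction targets, fixture round trips."""

import numpy as np
import pandas as pd
import pytest

from gstrial import qc, sim
from gstrial.kernels import vanraden_a_matrix


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        sim.SimConfig(snps_per_scaffold=1)
    with pytest.raises(ValueError):
        sim.SimConfig(maf_min=0.6)
    with pytest.raises(ValueError):
        sim.SimConfig(h2_additive=0.6, h2_epistatic=0.3, spatial_variance_fraction=0.2)
    with pytest.raises(ValueError):
        sim.SimConfig(n_blocks=0)


def test_rcbd_design_count_full_scale():
    cfg = sim.SimConfig()  # study defaults: 94 mothers x 5 per block x 8 blocks
    assert cfg.n_trees == 3760


def test_founder_positions_strictly_increasing_and_maf_floor(tiny_config):
    panel = sim.simulate_founder_haplotypes(tiny_config)
    for _, sub in panel.locus_info.groupby("scaffold"):
        assert (np.diff(sub["pos"]) > 0).all()
    freqs = panel.alleles.mean(axis=0)
    maf = np.minimum(freqs, 1 - freqs)
    assert (maf >= tiny_config.maf_min - 1e-12).all()


def test_duplicate_positions_rejected():
    info = pd.DataFrame({"scaffold": ["s1", "s1"], "pos": [10, 10], "freq": [0.5, 0.5]})
    alleles = np.array([[0, 1], [1, 0]], dtype=np.uint8)
    with pytest.raises(ValueError, match="strictly increasing"):
        sim.HaplotypePanel(alleles=alleles, locus_info=info)


def test_founder_ld_decays_with_distance():
    """Mean pairwise r2 at distances beyond 5 x ld_decay_bp is < 0.05
    (averaged over independent seeds)."""
    far_r2 = []
    for seed in range(20):
        cfg = sim.SimConfig(
            n_mothers=5, progeny_per_family_per_block=1, n_blocks=1,
            n_founder_haplotypes=120, n_scaffolds=4, snps_per_scaffold=25,
            scaffold_length_bp=30_000, ld_decay_bp=2000.0, seed=seed,
        )
        panel = sim.simulate_founder_haplotypes(cfg)
        H = panel.alleles.astype(float)
        for _, sub in panel.locus_info.groupby("scaffold"):
            idx = sub.index.to_numpy()
            pos = sub["pos"].to_numpy(float)
            X = H[:, idx]
            sd = X.std(axis=0)
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    if pos[b] - pos[a] > 5 * cfg.ld_decay_bp and sd[a] > 0 and sd[b] > 0:
                        r = np.corrcoef(X[:, a], X[:, b])[0, 1]
                        far_r2.append(r * r)
    assert np.mean(far_r2) < 0.05


def test_progeny_mendelian_and_counts(tiny_config, tiny_study):
    phase, codes, ped, pheno, panel, _ = tiny_study
    assert len(ped) == tiny_config.n_trees
    # each offspring's maternal gamete allele exists in the mother's genotype
    cfg = tiny_config
    rng_mating = cfg.rng("mating")
    mother_haps = rng_mating.choice(panel.n_haplotypes, size=(cfg.n_mothers, 2),
                                    replace=False)
    check = np.random.default_rng(0).choice(len(ped), 40, replace=False)
    for i in check:
        mom = int(ped["mother_id"].iloc[i].split("_")[1]) - 1
        ma, mb = mother_haps[mom]
        m_alleles = np.stack([panel.alleles[ma], panel.alleles[mb]])
        carried = phase[i, :, 0]
        assert np.all((carried == m_alleles[0]) | (carried == m_alleles[1]))


def test_progeny_too_many_mothers_rejected(tiny_config):
    panel = sim.simulate_founder_haplotypes(tiny_config)
    from dataclasses import asdict
    bad = sim.SimConfig(**{**asdict(tiny_config), "n_mothers": 200})
    with pytest.raises(ValueError, match="founder"):
        sim.simulate_progeny(panel, bad)


def test_half_sib_relationship_near_quarter():
    """VanRaden mean relationship: ~0.25 within half-sib families, ~0 for
    non-sibs (averaged over seeds)."""
    within_all, between_all = [], []
    for seed in range(5):
        cfg = sim.SimConfig(
            n_mothers=12, progeny_per_family_per_block=10, n_blocks=1,
            n_founder_haplotypes=200, n_scaffolds=20, snps_per_scaffold=15,
            scaffold_length_bp=20_000, seed=seed,
        )
        panel = sim.simulate_founder_haplotypes(cfg)
        phase, ped = sim.simulate_progeny(panel, cfg)
        codes = sim.codes_from_phase(phase).astype(float)
        A = vanraden_a_matrix(codes).matrix
        moms = ped["mother_id"].to_numpy()
        same = moms[:, None] == moms[None, :]
        off = ~np.eye(len(A), dtype=bool)
        within_all.append(A[same & off].mean())
        between_all.append(A[~same].mean())
    assert abs(np.mean(within_all) - 0.25) < 0.05
    assert abs(np.mean(between_all)) < 0.05


def test_trait_zero_heritability_constant_genetic(tiny_study, tiny_config):
    from dataclasses import asdict
    _, codes, *_ = tiny_study
    cfg = sim.SimConfig(**{**asdict(tiny_config), "h2_additive": 0.0,
                           "h2_epistatic": 0.0})
    arch, genetic = sim.simulate_trait(codes, cfg)
    assert np.allclose(genetic, arch.intercept)


def test_trait_variance_fractions_and_slope():
    """Planted additive fraction is realized and phenotype regresses on the
    true genetic value with slope ~1."""
    cfg = sim.SimConfig(
        n_mothers=25, progeny_per_family_per_block=10, n_blocks=8,
        n_founder_haplotypes=100, n_scaffolds=20, snps_per_scaffold=15,
        scaffold_length_bp=20_000, n_qtl_additive=50, h2_additive=0.35,
        spatial_variance_fraction=0.0, phenotype_missing_rate=0.0, seed=17,
    )
    panel = sim.simulate_founder_haplotypes(cfg)
    phase, ped = sim.simulate_progeny(panel, cfg)
    codes = sim.codes_from_phase(phase)
    arch, genetic = sim.simulate_trait(codes, cfg)
    assert abs(genetic.var() - 0.35) < 0.05
    tab = sim.simulate_field(genetic, ped, cfg, arch, trait_name="T")
    y = tab["T"].to_numpy()
    slope = np.polyfit(genetic, y, 1)[0]
    assert abs(slope - 1.0) < 0.1
    h2_realized = genetic.var() / y.var()
    assert 0.30 <= h2_realized <= 0.40


def test_qtl_count_exceeding_loci_rejected(tiny_study, tiny_config):
    from dataclasses import asdict
    _, codes, *_ = tiny_study
    cfg = sim.SimConfig(**{**asdict(tiny_config), "n_qtl_additive": 10**6})
    with pytest.raises(ValueError, match="exceeds"):
        sim.simulate_trait(codes, cfg)


def test_bimodal_major_qtl_produces_bimodality():
    """With a dominant major QTL the adjusted-phenotype histogram separates
    into two components (GMM means far apart relative to within-spread)."""
    cfg = sim.SimConfig(
        n_mothers=30, progeny_per_family_per_block=8, n_blocks=4,
        n_founder_haplotypes=120, n_scaffolds=20, snps_per_scaffold=15,
        scaffold_length_bp=20_000, n_qtl_additive=20, h2_additive=0.8,
        spatial_variance_fraction=0.0, phenotype_missing_rate=0.0,
        bimodal_major_qtl=True, seed=23,
    )
    panel = sim.simulate_founder_haplotypes(cfg)
    phase, ped = sim.simulate_progeny(panel, cfg)
    arch, genetic = sim.simulate_trait(sim.codes_from_phase(phase), cfg)
    tab = sim.simulate_field(genetic, ped, cfg, arch, trait_name="T")
    y = tab["T"].dropna().to_numpy().reshape(-1, 1)
    from sklearn.mixture import GaussianMixture
    g2 = GaussianMixture(2, random_state=0).fit(y)
    g1 = GaussianMixture(1, random_state=0).fit(y)
    # Ashman's D > 2 is the usual two-component bimodality criterion
    mu = g2.means_.ravel()
    s2 = g2.covariances_.ravel()
    ashman_d = np.sqrt(2.0) * abs(mu[1] - mu[0]) / np.sqrt(s2.sum())
    assert g2.bic(y) < g1.bic(y)
    assert ashman_d > 2.0


def test_field_rcbd_structure_and_missingness(tiny_study, tiny_config):
    _, _, ped, pheno, _, _ = tiny_study
    cfg = tiny_config
    # every family appears exactly progeny_per_family_per_block times per block
    counts = pheno.groupby(["block", "mother_id"]).size()
    assert (counts == cfg.progeny_per_family_per_block).all()
    # no two trees share a grid cell
    assert not pheno.duplicated(subset=["row", "col"]).any()
    miss = pheno["D7"].isna().mean()
    n = len(pheno)
    se = np.sqrt(cfg.phenotype_missing_rate * (1 - cfg.phenotype_missing_rate) / n)
    assert abs(miss - cfg.phenotype_missing_rate) < 4 * se + 1e-9


def test_spatial_variance_zero_gives_iid_noise():
    """With no planted surface the fitted spline explains <5% of variance."""
    from gstrial import spatial
    frac = []
    for seed in range(3):
        cfg = sim.SimConfig(
            n_mothers=20, progeny_per_family_per_block=5, n_blocks=4,
            n_founder_haplotypes=80, n_scaffolds=10, snps_per_scaffold=12,
            scaffold_length_bp=15_000, h2_additive=0.3,
            spatial_variance_fraction=0.0, phenotype_missing_rate=0.0, seed=seed,
        )
        panel = sim.simulate_founder_haplotypes(cfg)
        phase, ped = sim.simulate_progeny(panel, cfg)
        arch, genetic = sim.simulate_trait(sim.codes_from_phase(phase), cfg)
        tab = sim.simulate_field(genetic, ped, cfg, arch, trait_name="T")
        model = spatial.fit_spatial_spline(tab, "T")
        frac.append(model.fitted.var() / tab["T"].var())
    assert np.mean(frac) < 0.05


def test_fixture_round_trip_and_determinism(tmp_path, tiny_study, tiny_config):
    phase, codes, ped, pheno, panel, _ = tiny_study
    files = sim.write_fixture(phase, panel.locus_info, pheno, tmp_path / "fx",
                              config=tiny_config)
    g = qc.read_vcf(files["vcf"])
    order = np.lexsort((panel.locus_info["pos"].to_numpy(),
                        panel.locus_info["scaffold"].to_numpy()))
    assert np.array_equal(codes[:, order], g.codes.astype(int))
    assert g.phase is not None
    assert np.array_equal(phase[:, order], g.phase)  # 0|1 vs 1|0 preserved
    # resimulation from the same config reproduces the VCF byte-identically
    phase2, _, _, pheno2, panel2, _ = sim.simulate_study(tiny_config)
    files2 = sim.write_fixture(phase2, panel2.locus_info, pheno2,
                               tmp_path / "fx2", config=tiny_config)
    assert files["vcf"].read_bytes() == files2["vcf"].read_bytes()


def test_fixture_id_mismatch_rejected(tmp_path, tiny_study):
    phase, _, _, pheno, panel, _ = tiny_study
    with pytest.raises(ValueError, match="match"):
        sim.write_fixture(phase[:10], panel.locus_info, pheno, tmp_path / "bad")
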