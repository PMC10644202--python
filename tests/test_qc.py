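"""Genotype QC: VCF coding, filters against enumeration oracles, PCA, LD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

from gstrial import qc


def _gm(codes, scaffolds=None, positions=None, phase=None):
    codes = np.asarray(codes, float)
    n, m = codes.shape
    loci = pd.DataFrame({
        "scaffold": scaffolds if scaffolds is not None else ["s1"] * m,
        "pos": positions if positions is not None else np.arange(1, m + 1),
        "ref": "A", "alt": "G",
    })
    return qc.GenotypeMatrix(samples=[f"i{k}" for k in range(n)], loci=loci,
                             codes=codes, phase=phase)


# ---------------------------------------------------------------- VCF reading

def test_read_vcf_coding_missing_and_multiallelic(tmp_path):
    vcf = tmp_path / "t.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=s1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\n"
        "s1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "s1\t200\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/2\n"
        "s1\t300\t.\tA\tG\t.\tPASS\t.\tGT\t./.\t0/0\t1/1\n"
    )
    g = qc.read_vcf(vcf)
    assert g.n_loci == 2  # triallelic record dropped
    assert list(g.loci["pos"]) == [100, 300]
    assert np.array_equal(g.codes[:, 0], [-1.0, 0.0, 1.0])
    assert np.isnan(g.codes[0, 1]) and g.codes[1, 1] == -1.0 and g.codes[2, 1] == 1.0


# ------------------------------------------------------------------ HWE test

def _hwe_oracle(n_het, n_hom_minor, n_hom_major):
    """Direct enumeration over all genotype configurations with the same
    sample size and minor-allele count."""
    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het

    def prob(h):
        hm = (n_minor - h) // 2
        hM = n - h - hm
        return np.exp(
            gammaln(n + 1) - gammaln(h + 1) - gammaln(hm + 1) - gammaln(hM + 1)
            + h * np.log(2) + gammaln(n_minor + 1) + gammaln(2 * n - n_minor + 1)
            - gammaln(2 * n + 1)
        )

    configs = [h for h in range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)]
    probs = {h: prob(h) for h in configs}
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    return sum(v / total for v in probs.values() if v / total <= p_obs * (1 + 1e-12))


@given(st.integers(1, 50), st.data())
@settings(max_examples=60, deadline=None, derandomize=True)
def test_hwe_exact_matches_enumeration(n, data):
    n_hom_minor = data.draw(st.integers(0, n))
    n_het = data.draw(st.integers(0, n - n_hom_minor))
    n_hom_major = n - n_hom_minor - n_het
    if 2 * n_hom_minor + n_het > n:  # keep "minor" the minor allele
        n_hom_minor, n_hom_major = n_hom_major, n_hom_minor
    got = qc.hwe_exact_test(n_het, n_hom_minor, n_hom_major)
    want = _hwe_oracle(n_het, n_hom_minor, n_hom_major)
    assert got == pytest.approx(want, abs=1e-10)


def test_hwe_extreme_case_removed_by_filter():
    """A locus with zero heterozygotes split evenly between the homozygote
    classes grossly violates HWE; at n=20 the exact p falls below 0.001 and
    the site filter removes it (at n=10 the enumeration gives p = 0.00136,
    just above the threshold)."""
    assert qc.hwe_exact_test(0, 5, 5) == pytest.approx(0.0013639611, abs=1e-9)
    assert qc.hwe_exact_test(0, 10, 10) < 0.001
    col = np.array([-1.0] * 10 + [1.0] * 10)
    balanced = np.array([-1.0] * 6 + [0.0] * 8 + [1.0] * 6)
    g = _gm(np.column_stack([col, balanced]))
    kept = qc.filter_sites(g, max_missing=0.95, maf_min=0.05, hwe_p_min=0.001)
    assert kept.n_loci == 1 and kept.loci["pos"].iloc[0] == 2


def test_filter_sites_maf_and_missingness():
    rng = np.random.default_rng(0)
    good = rng.integers(-1, 2, size=(40, 1)).astype(float)
    rare = np.full((40, 1), -1.0); rare[:3] = 0.0          # maf 0.0375 < 0.05
    gappy = good.copy(); gappy[:4] = np.nan                 # call rate 0.9 < 0.95
    g = _gm(np.column_stack([good, rare, gappy]))
    kept = qc.filter_sites(g, 0.95, 0.05, 0.0)
    assert list(kept.loci["pos"]) == [1]


def test_filter_sites_idempotent():
    rng = np.random.default_rng(1)
    codes = rng.choice([-1.0, 0.0, 1.0, np.nan], size=(60, 40),
                       p=[0.3, 0.3, 0.3, 0.1])
    g = _gm(codes)
    once = qc.filter_sites(g, 0.9, 0.05, 0.001)
    twice = qc.filter_sites(once, 0.9, 0.05, 0.001)
    assert np.array_equal(once.codes, twice.codes, equal_nan=True)


def test_filter_samples():
    codes = np.full((3, 20), 0.0)
    codes[0, :14] = np.nan   # 70% missing -> dropped at 0.65
    g = _gm(codes)
    kept = qc.filter_samples(g, 0.65)
    assert kept.samples == ["i1", "i2"]


def test_remove_solitary_snps():
    g = _gm(np.zeros((4, 3)), scaffolds=["s1", "s1", "s2"], positions=[10, 20, 30])
    kept = qc.remove_solitary_snps(g)
    assert list(kept.loci["scaffold"]) == ["s1", "s1"]


@pytest.mark.parametrize("positions, expected", [
    ([100, 900, 1200], [100, 1200]),   # greedy rule trace
    ([100, 1200], [100, 1200]),
    ([100, 1099, 1100], [100, 1100]),
])
def test_thin_by_distance_greedy(positions, expected):
    g = _gm(np.zeros((2, len(positions))), positions=positions)
    kept = qc.thin_by_distance(g, 1000)
    assert list(kept.loci["pos"]) == expected


def test_thin_by_distance_per_scaffold_and_invariant():
    g = _gm(np.zeros((2, 2)), scaffolds=["s1", "s2"], positions=[100, 150])
    assert qc.thin_by_distance(g, 1000).n_loci == 2
    rng = np.random.default_rng(3)
    pos = np.sort(rng.choice(50_000, 200, replace=False))
    g2 = _gm(np.zeros((2, 200)), positions=pos)
    thinned = qc.thin_by_distance(g2, 1000)
    assert (np.diff(thinned.loci["pos"]) >= 1000).all()


def test_impute_missing_mean_mode_and_errors():
    g = _gm(np.array([[-1.0, 1.0], [1.0, 1.0], [np.nan, np.nan]]))
    mean = qc.impute_missing(g, "mean")
    assert mean.codes[2, 0] == pytest.approx(0.0)
    mode = qc.impute_missing(g, "mode")
    assert mode.codes[2, 1] == 1.0
    full = _gm(np.array([[1.0, 0.0], [0.0, -1.0]]))
    assert np.array_equal(qc.impute_missing(full, "mean").codes, full.codes)
    allmiss = _gm(np.array([[np.nan], [np.nan]]))
    with pytest.raises(ValueError, match="all genotypes missing"):
        qc.impute_missing(allmiss, "mean")


# ---------------------------------------------------------------------- PCA

def test_pca_duplicates_variance_and_distances():
    rng = np.random.default_rng(4)
    X = rng.integers(-1, 2, size=(20, 50)).astype(float)
    X[5] = X[4]  # duplicated individual
    coords, pct = qc.pca(X)
    assert np.allclose(coords[4], coords[5], atol=1e-8)
    assert pct.sum() <= 100 + 1e-9
    assert (np.diff(pct) <= 1e-9).all()
    # coordinates reproduce pairwise distances of the centered data
    Xc = X - X.mean(axis=0)
    from scipy.spatial.distance import pdist
    assert np.allclose(pdist(coords), pdist(Xc), atol=1e-8)


def test_pca_separates_two_founder_pools():
    rng = np.random.default_rng(6)
    p1 = rng.uniform(0.1, 0.9, 120)
    p2 = np.clip(p1 + rng.choice([-1, 1], 120) * 0.35, 0.02, 0.98)
    A = rng.binomial(2, p1, (40, 120)) - 1.0
    B = rng.binomial(2, p2, (40, 120)) - 1.0
    coords, _ = qc.pca(np.vstack([A, B]))
    from sklearn.metrics import silhouette_score
    labels = np.array([0] * 40 + [1] * 40)
    assert silhouette_score(coords[:, :1], labels) > 0.5


# ----------------------------------------------------------------------- LD

def test_pairwise_ld_oracle_and_duplicates():
    rng = np.random.default_rng(7)
    X = rng.integers(-1, 2, size=(50, 6)).astype(float)
    X[:, 3] = X[:, 2]  # perfect duplicate pair
    g = _gm(X, positions=[10, 500, 900, 1400, 2000, 2600])
    ld = qc.pairwise_ld(g)
    t = ld.table
    dup = t[(t.dist == 500) & (t.r2 > 0.999)]
    assert len(dup) >= 1
    # every r2 equals the brute-force squared correlation
    pos = g.loci["pos"].to_numpy()
    for a in range(6):
        for b in range(a + 1, 6):
            want = np.corrcoef(X[:, a], X[:, b])[0, 1] ** 2
            got = t[(t.dist == pos[b] - pos[a])].r2.to_numpy()
            assert np.any(np.isclose(got, want, atol=1e-12))


def test_pairwise_ld_null_mean_near_one_over_n():
    rng = np.random.default_rng(8)
    n = 300
    X = rng.binomial(2, 0.4, size=(n, 150)) - 1.0
    g = _gm(X, positions=np.arange(1, 151) * 100)
    mean_r2 = qc.pairwise_ld(g).table["r2"].mean()
    assert mean_r2 == pytest.approx(1 / (n - 1), rel=0.2)


def test_ld_decay_analytic_crossing():
    """Noise-free r2(d) = exp(-d/delta) crosses 0.1 at delta ln 10."""
    delta = 2000.0
    d = np.linspace(50, 12000, 400)
    table = pd.DataFrame({"scaffold": "s1", "dist": d, "r2": np.exp(-d / delta)})
    decay, _, _ = qc.ld_decay(qc.LdTable(table=table))
    assert decay == pytest.approx(delta * np.log(10), rel=0.02)


def test_ld_decay_no_crossing_and_few_pairs():
    d = np.linspace(50, 5000, 100)
    high = pd.DataFrame({"scaffold": "s1", "dist": d, "r2": 0.5 + 0.1 * np.exp(-d / 800)})
    decay, _, _ = qc.ld_decay(qc.LdTable(table=high))
    assert decay is None
    tiny = pd.DataFrame({"scaffold": "s1", "dist": d[:10], "r2": np.exp(-d[:10] / 800)})
    with pytest.raises(ValueError, match="20"):
        qc.ld_decay(qc.LdTable(table=tiny))


# ------------------------------------------------------------ genome coverage

def test_genome_size_and_coverage_worked_examples():
    size, cov = qc.estimate_genome_coverage(0.372, 2236, 8709)
    assert size == pytest.approx(363_816_000)
    assert round(100 * cov, 2) == 5.35
    size1, _ = qc.estimate_genome_coverage(1.0, 1000, 10)
    assert size1 == pytest.approx(978_000_000)
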