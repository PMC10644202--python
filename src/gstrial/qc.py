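"""Genotype-level QC: VCF reading, site/sample filters, coding, imputation,
PCA, and linkage-disequilibrium decay summaries.

Genotype coding follows the -1/0/1 convention (homozygous reference -1,
heterozygous 0, homozygous alternative 1). Site filters mirror the VCFtools
semantics: ``--max-missing x`` keeps sites with a called proportion >= x;
MAF and exact Hardy-Weinberg thresholds are lower bounds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "LdTable",
    "read_vcf",
    "hwe_exact_test",
    "filter_sites",
    "filter_samples",
    "remove_solitary_snps",
    "thin_by_distance",
    "impute_missing",
    "pca",
    "pairwise_ld",
    "loess_fit",
    "ld_decay",
    "estimate_genome_coverage",
]


@dataclass
class GenotypeMatrix:
    """Samples × biallelic SNPs with -1/0/1 codes (NaN = missing).

    ``loci`` holds scaffold, 1-based position, ref and alt alleles, sorted
    by (scaffold, position). ``phase`` optionally stores per-gamete
    alternative-allele indicators (n × m × 2); where present,
    ``phase.sum(axis=2) - 1`` equals the code.
    """

    samples: list
    loci: pd.DataFrame
    codes: np.ndarray
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        vals = self.codes[~np.isnan(self.codes)]
        if vals.size and not np.isin(vals, [-1.0, 0.0, 1.0]).all():
            raise ValueError("codes must be in {-1, 0, 1} or NaN")
        if self.codes.shape != (len(self.samples), len(self.loci)):
            raise ValueError("codes shape inconsistent with samples/loci")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def take_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=self.samples,
            loci=self.loci.iloc[idx].reset_index(drop=True),
            codes=self.codes[:, idx],
            phase=self.phase[:, idx] if self.phase is not None else None,
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            loci=self.loci,
            codes=self.codes[idx],
            phase=self.phase[idx] if self.phase is not None else None,
        )


@dataclass
class LdTable:
    """Within-scaffold pairwise r² against inter-SNP distance (bp)."""

    table: pd.DataFrame  # columns: scaffold, dist, r2

    def __post_init__(self) -> None:
        t = self.table
        if len(t) and ((t["r2"] < -1e-12).any() or (t["r2"] > 1 + 1e-12).any()):
            raise ValueError("r2 outside [0, 1]")
        if len(t) and (t["dist"] <= 0).any():
            raise ValueError("non-positive inter-SNP distance")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into coded genotypes, keeping biallelic SNPs only.

    Multiallelic or non-SNP records are dropped (count logged). ``./.``
    becomes NaN. Phase is retained when every genotype in the file is
    phased; otherwise the phase layer is omitted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    codes_rows, phase_rows, meta = [], [], []
    n_dropped = 0
    all_phased = True
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_dropped += 1
            continue
        g = np.array([row[:3] for row in var.genotypes], dtype=int)  # a0, a1, phased
        a0, a1 = g[:, 0].astype(float), g[:, 1].astype(float)
        miss = (g[:, 0] < 0) | (g[:, 1] < 0)
        code = a0 + a1 - 1.0
        code[miss] = np.nan
        codes_rows.append(code)
        phase_rows.append(np.stack([g[:, 0], g[:, 1]], axis=1))
        if not np.all(g[~miss, 2] == 1):
            all_phased = False
        meta.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    if n_dropped:
        logger.info("read_vcf: dropped %d multiallelic/non-SNP records", n_dropped)
    if not meta:
        raise ValueError(f"no biallelic SNP records in {path}")
    loci = pd.DataFrame(meta, columns=["scaffold", "pos", "ref", "alt"])
    codes = np.array(codes_rows).T
    phase = None
    if all_phased:
        phase = np.transpose(np.array(phase_rows, dtype=np.int8), (1, 0, 2))
    order = np.lexsort((loci["pos"].to_numpy(), loci["scaffold"].to_numpy()))
    g = GenotypeMatrix(samples=samples, loci=loci, codes=codes, phase=phase)
    return g.take_loci(order)


def hwe_exact_test(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg test p-value by full enumeration.

    Sums the probabilities of all heterozygote counts (given the sample
    size and minor-allele count) whose conditional probability does not
    exceed that of the observed configuration.
    """
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het

    def log_prob(h):
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        return (
            gammaln(n + 1) - gammaln(h + 1) - gammaln(hom_min + 1) - gammaln(hom_maj + 1)
            + h * np.log(2.0)
            + gammaln(n_minor + 1) + gammaln(2 * n - n_minor + 1) - gammaln(2 * n + 1)
        )

    hets = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    logs = np.array([log_prob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[np.nonzero(hets == n_het)[0][0]]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def _site_stats(codes: np.ndarray):
    called = ~np.isnan(codes)
    n_called = called.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq_alt = (np.nansum(codes, axis=0) + n_called) / (2 * np.maximum(n_called, 1))
    maf = np.minimum(freq_alt, 1 - freq_alt)
    return called, n_called, maf


def filter_sites(
    g: GenotypeMatrix,
    max_missing: float = 0.95,
    maf_min: float = 0.05,
    hwe_p_min: float = 0.001,
) -> GenotypeMatrix:
    """Keep sites called in >= ``max_missing`` of samples (VCFtools sense),
    with MAF >= ``maf_min`` and exact-HWE p >= ``hwe_p_min``."""
    if g.n_loci == 0:
        raise ValueError("empty genotype matrix")
    called, n_called, maf = _site_stats(g.codes)
    keep = (n_called / g.n_samples >= max_missing) & (maf >= maf_min)
    for j in np.nonzero(keep)[0]:
        col = g.codes[called[:, j], j]
        n_het = int((col == 0).sum())
        n_ref = int((col == -1).sum())
        n_alt = int((col == 1).sum())
        hom_minor, hom_major = sorted((n_ref, n_alt))
        if hwe_exact_test(n_het, hom_minor, hom_major) < hwe_p_min:
            keep[j] = False
    if not keep.any():
        warnings.warn("filter_sites removed every locus")
    return g.take_loci(np.nonzero(keep)[0])


def filter_samples(g: GenotypeMatrix, max_sample_missing: float = 0.65) -> GenotypeMatrix:
    """Drop samples whose missing-genotype fraction exceeds the threshold."""
    miss = np.isnan(g.codes).mean(axis=1)
    keep = np.nonzero(miss <= max_sample_missing)[0]
    if keep.size == 0:
        warnings.warn("filter_samples removed every sample")
    return g.take_samples(keep)


def remove_solitary_snps(g: GenotypeMatrix) -> GenotypeMatrix:
    """Remove SNPs that are the only one on their scaffold."""
    if g.n_loci == 0:
        return g
    counts = g.loci.groupby("scaffold")["pos"].transform("size").to_numpy()
    return g.take_loci(np.nonzero(counts >= 2)[0])


def thin_by_distance(g: GenotypeMatrix, min_bp: int = 1000) -> GenotypeMatrix:
    """Greedy left-to-right thinning: within each scaffold keep a locus iff
    it lies >= ``min_bp`` from the last kept locus."""
    keep = []
    for scaf, sub in g.loci.groupby("scaffold", sort=False):
        last = -np.inf
        for idx, pos in zip(sub.index, sub["pos"]):
            if pos - last >= min_bp:
                keep.append(idx)
                last = pos
    return g.take_loci(np.array(sorted(keep), dtype=int))


def impute_missing(g: GenotypeMatrix, method: str = "mean") -> GenotypeMatrix:
    """Replace missing codes by the per-locus mean or mode.

    A simple single-site imputation standing in for haplotype-based
    imputation; mean imputation leaves codes off the -1/0/1 grid, so the
    result drops the integer-code invariant check by construction (mode
    keeps it).
    """
    codes = g.codes.copy()
    miss = np.isnan(codes)
    if miss.all(axis=0).any():
        raise ValueError("locus with all genotypes missing cannot be imputed")
    if method == "mean":
        fill = np.nanmean(codes, axis=0)
    elif method == "mode":
        fill = np.empty(g.n_loci)
        for j in range(g.n_loci):
            col = codes[~miss[:, j], j]
            vals, counts = np.unique(col, return_counts=True)
            fill[j] = vals[np.argmax(counts)]
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    codes[miss] = np.broadcast_to(fill, codes.shape)[miss]
    out = GenotypeMatrix.__new__(GenotypeMatrix)
    out.samples = g.samples
    out.loci = g.loci
    out.codes = codes
    out.phase = g.phase
    return out


def pca(g: GenotypeMatrix | np.ndarray, n_components: int | None = None):
    """Centered (unscaled) PCA of the coded genotypes, prcomp-style.

    Returns ``(coordinates, pct_var)`` with variance explained per
    component in percent.
    """
    X = g.codes if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    if np.isnan(X).any():
        raise ValueError("pca requires complete genotypes; impute first")
    n = X.shape[0]
    if n < 2:
        raise ValueError("pca needs at least 2 samples")
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    k = n_components or len(s)
    coords = U[:, :k] * s[:k]
    var = s**2 / (n - 1)
    pct = 100.0 * var[:k] / var.sum()
    return coords, pct


def pairwise_ld(
    g: GenotypeMatrix, max_pairs_per_scaffold: int = 200_000
) -> LdTable:
    """Composite-LD r² (squared genotype correlation) for within-scaffold
    SNP pairs.

    When a scaffold's full pair count exceeds the cap, the index-offset
    window is shrunk so that near pairs (small distances) are kept — the
    informative region for decay fitting. Monomorphic loci are skipped.
    """
    if np.isnan(g.codes).any():
        raise ValueError("pairwise_ld requires complete genotypes")
    rows = []
    for scaf, sub in g.loci.groupby("scaffold", sort=False):
        idx = sub.index.to_numpy()
        m = len(idx)
        if m < 2:
            continue
        X = g.codes[:, idx]
        sd = X.std(axis=0)
        pos = sub["pos"].to_numpy().astype(float)
        max_off = m - 1
        while max_off > 1 and sum(min(max_off, m - 1 - i) for i in range(m)) > max_pairs_per_scaffold:
            max_off -= 1
        Xc = (X - X.mean(axis=0))
        for off in range(1, max_off + 1):
            a = np.arange(0, m - off)
            b = a + off
            ok = (sd[a] > 0) & (sd[b] > 0)
            if not ok.all():
                logger.info("pairwise_ld: skipped %d monomorphic pairs on %s",
                            int((~ok).sum()), scaf)
            a, b = a[ok], b[ok]
            if len(a) == 0:
                continue
            num = (Xc[:, a] * Xc[:, b]).mean(axis=0)
            r = num / (sd[a] * sd[b])
            rows.append(pd.DataFrame({"scaffold": scaf, "dist": pos[b] - pos[a],
                                      "r2": r**2}))
    table = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=["scaffold", "dist", "r2"]))
    return LdTable(table=table)


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1 - np.abs(u) ** 3, 0, None) ** 3
    return w


def loess_fit(x: np.ndarray, y: np.ndarray, span: float, x_eval: np.ndarray,
              degree: int = 2) -> np.ndarray:
    """Local polynomial (default quadratic) regression with tricube weights."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    n = len(xs)
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)
    out = np.empty(len(x_eval))
    for i, x0 in enumerate(x_eval):
        d = np.abs(xs - x0)
        cut = np.partition(d, k - 1)[k - 1]
        sel = d <= cut
        w = _tricube(d[sel] / max(cut, 1e-300))
        pos = w > 0
        xw, yw, w = xs[sel][pos], ys[sel][pos], w[pos]
        if len(xw) <= degree:
            out[i] = np.average(ys[sel], weights=_tricube(d[sel] / max(cut, 1e-300)) + 1e-12)
            continue
        # weighted polynomial fit centred at x0 for conditioning
        scale = max(np.abs(xw - x0).max(), 1e-300)
        B = np.vander((xw - x0) / scale, degree + 1, increasing=True)
        W = w[:, None]
        coef, *_ = np.linalg.lstsq(B * np.sqrt(W), yw * np.sqrt(w), rcond=None)
        out[i] = coef[0]
    return out


_SPAN_GRID = np.arange(0.1, 1.01, 0.1)


def ld_decay(
    ld: LdTable,
    r2_cut: float = 0.1,
    span_grid: np.ndarray = _SPAN_GRID,
    n_grid: int = 400,
    cv_folds: int = 4,
    cv_max_points: int = 4000,
    seed: int = 0,
):
    """LD-decay distance: first crossing of the loess trend below ``r2_cut``.

    The loess span is chosen on a fixed grid by k-fold cross-validation
    minimizing RMSE (points subsampled beyond ``cv_max_points`` for the CV
    step only). Returns ``(decay_bp or None, (grid, fitted), span)``.
    """
    t = ld.table
    if len(t) < 20:
        raise ValueError("need at least 20 SNP pairs for a reliable LD fit")
    x = t["dist"].to_numpy(float)
    y = t["r2"].to_numpy(float)

    rng = np.random.default_rng(seed)
    if len(x) > cv_max_points:
        sub = rng.choice(len(x), size=cv_max_points, replace=False)
        xcv, ycv = x[sub], y[sub]
    else:
        xcv, ycv = x, y
    folds = rng.permutation(len(xcv)) % cv_folds
    best_span, best_rmse = None, np.inf
    for span in span_grid:
        sq = 0.0
        for f in range(cv_folds):
            tr, te = folds != f, folds == f
            pred = loess_fit(xcv[tr], ycv[tr], span, xcv[te])
            sq += np.sum((pred - ycv[te]) ** 2)
        rmse = np.sqrt(sq / len(xcv))
        if rmse < best_rmse:
            best_rmse, best_span = rmse, span

    grid = np.linspace(x.min(), x.max(), n_grid)
    fitted = loess_fit(x, y, best_span, grid)

    decay = None
    above = fitted >= r2_cut
    for i in range(1, len(grid)):
        if above[i - 1] and not above[i]:
            # linear interpolation within the grid cell
            f0, f1 = fitted[i - 1], fitted[i]
            decay = grid[i - 1] + (f0 - r2_cut) / (f0 - f1) * (grid[i] - grid[i - 1])
            break
    return decay, (grid, fitted), float(best_span)


def estimate_genome_coverage(c_value_pg: float, decay_bp: float, n_thinned_snps: int):
    """Genome size from the C-value (1 pg = 0.978e9 bp) and the fraction of
    it covered by ``n_thinned_snps`` windows of length ``decay_bp``.

    Returns ``(genome_size_bp, coverage_fraction)``.
    """
    if c_value_pg <= 0 or decay_bp <= 0 or n_thinned_snps <= 0:
        raise ValueError("inputs must be positive")
    genome_bp = c_value_pg * 0.978e9
    coverage = decay_bp * n_thinned_snps / genome_bp
    return genome_bp, coverage
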