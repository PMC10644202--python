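"""Single-locus mixed-model association scan and GWAS-based SNP selection.

The scan corrects for relatedness and population structure with a kinship
random effect plus leading principal components as fixed covariates. The
variance components of the SNP-free null model are estimated once by REML
via the spectral decomposition of the kinship matrix; every SNP is then
tested by generalized least squares on the rotated data (the single-
rotation EMMAX-style approximation). Benjamini–Hochberg q-values and LOD
scores accompany the Wald p-values; subsets of the k smallest p-values
drive marker selection within training folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kernels import KernelSpec, _reml_one_kernel
from .qc import pca as _pca

__all__ = ["GwasResult", "mixed_scan", "fdr_adjust", "select_top_k",
           "subset_overlap", "check_polymorphism"]

LOD_REPORT_THRESHOLD = 3.0


@dataclass
class GwasResult:
    """Per-SNP scan output plus metadata."""

    table: pd.DataFrame  # scaffold, pos, effect, se, p, q, lod
    n_samples: int
    n_pcs: int
    kinship_kind: str

    def __post_init__(self):
        p = self.table["p"].to_numpy()
        ok = ~np.isnan(p)
        if ok.any() and ((p[ok] < 0).any() or (p[ok] > 1).any()):
            raise ValueError("p-values outside [0, 1]")


def mixed_scan(
    y,
    X,
    kinship: KernelSpec,
    n_pcs: int = 4,
    loci: pd.DataFrame | None = None,
    pc_matrix: np.ndarray | None = None,
) -> GwasResult:
    """EMMAX-style mixed-model scan of every column of ``X``.

    The null model y = W delta + u + e (u with covariance proportional to
    the kinship, W = intercept + ``n_pcs`` genotype PCs) is fitted once by
    REML; each SNP is then added to W and tested by GLS on the
    eigen-rotated data. Monomorphic SNPs get p = NaN. LOD is the GLS
    likelihood ratio divided by 2 ln 10.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, m = X.shape
    if np.isnan(X).any():
        raise ValueError("complete genotypes required")
    K = kinship.matrix
    d_chk = np.linalg.eigvalsh(K)
    if d_chk.min() < -1e-6 * max(abs(d_chk).max(), 1.0):
        raise ValueError("kinship matrix not positive semidefinite")

    if pc_matrix is None and n_pcs > 0:
        coords, _ = _pca(X, n_components=n_pcs)
        pc_matrix = coords
    W = np.ones((n, 1)) if n_pcs == 0 else np.column_stack(
        [np.ones(n), pc_matrix[:, :n_pcs]]
    )
    q = W.shape[1]

    # Null-model variance ratio by REML on covariate-residualized data, then
    # a single rotation shared by every SNP test.
    resid = y - W @ np.linalg.lstsq(W, y, rcond=None)[0]
    _, s2u, s2e = _reml_one_kernel(resid, K)
    gamma = s2u / s2e if s2e > 0 else 1e8

    d, U = np.linalg.eigh(K + 1e-8 * np.eye(n))
    w = gamma * np.maximum(d, 0.0) + 1.0
    sw = 1.0 / np.sqrt(w)
    ys = (U.T @ y) * sw
    Ws = (U.T @ W) * sw[:, None]
    Xs = (U.T @ X) * sw[:, None]

    # residualize the SNPs and the phenotype on the covariates (GLS scale)
    Qw, Rw = np.linalg.qr(Ws)
    y_r = ys - Qw @ (Qw.T @ ys)
    X_r = Xs - Qw @ (Qw.T @ Xs)
    rss0 = float(y_r @ y_r)
    df = n - q - 1

    xtx = np.sum(X_r**2, axis=0)
    xty = X_r.T @ y_r
    mono = X.std(axis=0) == 0
    effect = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pvals = np.full(m, np.nan)
    lod = np.full(m, np.nan)
    ok = (~mono) & (xtx > 1e-12)
    b = np.zeros(m)
    b[ok] = xty[ok] / xtx[ok]
    rss1 = rss0 - b[ok] ** 2 * xtx[ok]
    rss1 = np.maximum(rss1, 1e-300)
    sigma2 = rss1 / df
    se_ok = np.sqrt(sigma2 / xtx[ok])
    t = b[ok] / se_ok
    effect[ok] = b[ok]
    se[ok] = se_ok
    pvals[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    lod[ok] = n * (np.log(rss0) - np.log(rss1)) / (2.0 * np.log(10.0))

    qvals = np.full(m, np.nan)
    qvals[ok] = fdr_adjust(pvals[ok])

    if loci is None:
        loci = pd.DataFrame({"scaffold": ["scaffold_1"] * m, "pos": np.arange(1, m + 1)})
    table = pd.DataFrame(
        {
            "scaffold": loci["scaffold"].to_numpy(),
            "pos": loci["pos"].to_numpy(),
            "effect": effect,
            "se": se,
            "p": pvals,
            "q": qvals,
            "lod": lod,
        }
    )
    return GwasResult(table=table, n_samples=n, n_pcs=n_pcs, kinship_kind=kinship.kind)


def fdr_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values: q_(i) = min_{j>=i} p_(j) m / j."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, float)
    return multipletests(p, method="fdr_bh")[1]


def select_top_k(result: GwasResult, k: int) -> np.ndarray:
    """Indices of the k smallest scan p-values, ties broken by genome order."""
    t = result.table
    p = t["p"].to_numpy()
    defined = np.nonzero(~np.isnan(p))[0]
    if k > len(defined):
        raise ValueError(f"k={k} exceeds {len(defined)} SNPs with defined p-values")
    sub = t.iloc[defined]
    order = np.lexsort(
        (sub["pos"].to_numpy(), sub["scaffold"].to_numpy(), p[defined])
    )
    return np.sort(defined[order[:k]])


def subset_overlap(sets) -> float:
    """Mean pairwise sharing percentage across training-fold SNP subsets."""
    sets = [set(np.asarray(s).tolist()) for s in sets]
    if len(sets) < 2:
        raise ValueError("need at least 2 folds")
    k = len(sets[0])
    if any(len(s) != k for s in sets):
        raise ValueError("unequal subset sizes across folds")
    shares = [
        len(sets[i] & sets[j]) / k * 100.0
        for i in range(len(sets))
        for j in range(i + 1, len(sets))
    ]
    return float(np.mean(shares))


def check_polymorphism(X_train, snp_idx):
    """Verify every selected SNP keeps >= 2 genotype classes in the fold.

    Returns ``(all_polymorphic, offending_indices)``.
    """
    X_train = np.asarray(X_train, float)
    snp_idx = np.asarray(snp_idx, int)
    offending = [int(j) for j in snp_idx
                 if len(np.unique(X_train[:, j])) < 2]
    return len(offending) == 0, offending
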