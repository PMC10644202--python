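"""Synthetic half-sib progeny-trial generator.

Emulates an open-pollinated progeny trial of a tropical timber tree: mother
trees sampled from a natural stand, open-pollinated families planted in a
randomized complete block design (RCBD), reduced-representation SNP
genotypes with distance-dependent linkage disequilibrium, additive and/or
epistatic trait architectures, a smooth micro-environmental field surface,
and phenotype missingness from thinning and mortality.

All randomness flows from a single master seed through named substreams, so
a :class:`SimConfig` fully determines every artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "HaplotypePanel",
    "TraitArchitecture",
    "simulate_founder_haplotypes",
    "simulate_progeny",
    "simulate_trait",
    "simulate_field",
    "simulate_study",
    "write_fixture",
]

_SUBSTREAMS = ("haplotypes", "mating", "recombination", "trait", "field", "missing")


@dataclass
class SimConfig:
    """Parameters of the simulated progeny trial.

    Defaults follow the study conditions this package benchmarks: 94
    open-pollinated half-sib families, 5 trees per family per block in 8
    RCBD blocks (3760 trees), ~18k biallelic SNPs spread over many scaffolds
    with LD decaying to r²≈0.1 within a few kb, narrow-sense heritability in
    the 0.27–0.41 band, 6 m × 3 m planting grid, and roughly a quarter of
    phenotypes lost to thinning/mortality.
    """

    n_mothers: int = 94
    progeny_per_family_per_block: int = 5
    n_blocks: int = 8
    n_founder_haplotypes: int = 400
    n_scaffolds: int = 300
    snps_per_scaffold: int = 60
    scaffold_length_bp: int = 60_000
    ld_decay_bp: float = 2300.0
    maf_min: float = 0.05
    n_qtl_additive: int = 100
    n_qtl_epistatic_pairs: int = 50
    h2_additive: float = 0.35
    h2_epistatic: float = 0.0
    spatial_variance_fraction: float = 0.15
    bimodal_major_qtl: bool = False
    row_spacing_m: float = 3.0
    col_spacing_m: float = 6.0
    phenotype_missing_rate: float = 0.23
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_mothers": self.n_mothers,
            "progeny_per_family_per_block": self.progeny_per_family_per_block,
            "n_blocks": self.n_blocks,
            "n_founder_haplotypes": self.n_founder_haplotypes,
            "n_scaffolds": self.n_scaffolds,
            "snps_per_scaffold": self.snps_per_scaffold,
            "scaffold_length_bp": self.scaffold_length_bp,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.snps_per_scaffold < 2:
            raise ValueError("snps_per_scaffold must be at least 2")
        if self.snps_per_scaffold > self.scaffold_length_bp:
            raise ValueError("more SNPs than base pairs on a scaffold")
        if not (0.0 < self.maf_min <= 0.5):
            raise ValueError("maf_min must lie in (0, 0.5]")
        for name in ("h2_additive", "h2_epistatic", "spatial_variance_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.h2_additive + self.h2_epistatic + self.spatial_variance_fraction >= 1.0:
            raise ValueError(
                "h2_additive + h2_epistatic + spatial_variance_fraction must be < 1"
            )
        if not (0.0 <= self.phenotype_missing_rate < 1.0):
            raise ValueError("phenotype_missing_rate must lie in [0, 1)")

    @property
    def n_trees(self) -> int:
        """Total planted trees in the RCBD (families × per-block copies × blocks)."""
        return self.n_mothers * self.progeny_per_family_per_block * self.n_blocks

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the master seed."""
        if stream not in _SUBSTREAMS:
            raise KeyError(f"unknown substream {stream!r}")
        idx = _SUBSTREAMS.index(stream)
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(idx,)))


@dataclass
class HaplotypePanel:
    """Founder haplotypes: binary allele matrix plus locus metadata."""

    alleles: np.ndarray  # (n_haplotypes, n_loci) uint8, 1 = alternative allele
    locus_info: pd.DataFrame  # columns: scaffold, pos, freq

    def __post_init__(self) -> None:
        for scaf, sub in self.locus_info.groupby("scaffold", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {scaf}")
        freqs = self.alleles.mean(axis=0)
        if np.any((freqs == 0.0) | (freqs == 1.0)):
            raise ValueError("monomorphic locus among founders")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]


@dataclass
class TraitArchitecture:
    """Realized genetic architecture of one simulated trait."""

    additive_qtl: np.ndarray          # locus indices
    additive_effects: np.ndarray      # effect per additive QTL (on -1/0/1 codes)
    epistatic_pairs: np.ndarray       # (k, 2) locus-index pairs
    epistatic_effects: np.ndarray     # interaction effect per pair
    intercept: float
    residual_sd: float
    spatial_surface: np.ndarray | None = None  # filled by simulate_field


def _binary_markov_haplotypes(
    rng: np.random.Generator,
    n_hap: int,
    freqs: np.ndarray,
    pos: np.ndarray,
    ld_decay_bp: float,
) -> np.ndarray:
    """Haplotypes from a first-order binary Markov chain along a scaffold.

    Adjacent-locus allele correlation is exp(-d / ld_decay_bp); transition
    probabilities are solved to hit both the target marginal frequency and
    the target correlation (clipped to [0, 1] where the pair is infeasible).
    """
    m = len(freqs)
    H = np.empty((n_hap, m), dtype=np.uint8)
    H[:, 0] = rng.random(n_hap) < freqs[0]
    for j in range(1, m):
        p_prev, p = freqs[j - 1], freqs[j]
        rho = np.exp(-(pos[j] - pos[j - 1]) / ld_decay_bp)
        q_prev, q = 1.0 - p_prev, 1.0 - p
        t11 = np.clip(p + rho * np.sqrt(p * q * q_prev / p_prev), 0.0, 1.0)
        t01 = np.clip(p - rho * np.sqrt(p * q * p_prev / q_prev), 0.0, 1.0)
        prev = H[:, j - 1].astype(bool)
        u = rng.random(n_hap)
        H[:, j] = np.where(prev, u < t11, u < t01)
    return H


def _enforce_maf(rng: np.random.Generator, H: np.ndarray, maf_min: float) -> None:
    """Flip random haplotypes so every locus meets the founder MAF floor."""
    n = H.shape[0]
    need = int(np.ceil(maf_min * n))
    counts = H.sum(axis=0)
    for j in np.nonzero((counts < need) | (counts > n - need))[0]:
        c = counts[j]
        minor_is_alt = c <= n - c
        k_minor = c if minor_is_alt else n - c
        deficit = need - k_minor
        major_val = 0 if minor_is_alt else 1
        carriers = np.nonzero(H[:, j] == major_val)[0]
        flip = rng.choice(carriers, size=deficit, replace=False)
        H[flip, j] = 1 - major_val


def simulate_founder_haplotypes(config: SimConfig) -> HaplotypePanel:
    """Generate the founder haplotype panel with distance-dependent LD.

    Per scaffold, SNP positions are drawn without replacement (strictly
    increasing), target allele frequencies uniformly on
    [maf_min + 0.05, 1 - maf_min - 0.05], and haplotypes follow a binary
    Markov chain whose adjacent-locus correlation decays as
    exp(-d/ld_decay_bp). Any locus whose realized minor-allele frequency
    falls below ``maf_min`` is repaired by flipping random major-allele
    carriers.
    """
    rng = config.rng("haplotypes")
    lo = min(config.maf_min + 0.05, 0.45)
    blocks, frames = [], []
    for s in range(config.n_scaffolds):
        pos = np.sort(
            rng.choice(config.scaffold_length_bp, size=config.snps_per_scaffold, replace=False)
        ) + 1
        freqs = rng.uniform(lo, 1.0 - lo, size=config.snps_per_scaffold)
        H = _binary_markov_haplotypes(
            rng, config.n_founder_haplotypes, freqs, pos.astype(float), config.ld_decay_bp
        )
        _enforce_maf(rng, H, config.maf_min)
        blocks.append(H)
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": f"scaffold_{s + 1}",
                    "pos": pos,
                    "freq": H.mean(axis=0),
                }
            )
        )
    alleles = np.concatenate(blocks, axis=1)
    locus_info = pd.concat(frames, ignore_index=True)
    return HaplotypePanel(alleles=alleles, locus_info=locus_info)


def _recombine(
    rng: np.random.Generator,
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    scaffold_bounds: np.ndarray,
) -> np.ndarray:
    """One gamete: Poisson crossovers (rate 1 per scaffold), random start phase."""
    gamete = np.empty_like(hap_a)
    for k in range(len(scaffold_bounds) - 1):
        lo, hi = scaffold_bounds[k], scaffold_bounds[k + 1]
        m = hi - lo
        n_x = rng.poisson(1.0)
        cuts = np.sort(rng.integers(1, m, size=n_x)) if n_x and m > 1 else np.empty(0, int)
        use_a = bool(rng.integers(2))
        prev = 0
        for cut in list(cuts) + [m]:
            src = hap_a if use_a else hap_b
            gamete[lo + prev : lo + cut] = src[lo + prev : lo + cut]
            use_a = not use_a
            prev = cut
    return gamete


def _scaffold_bounds(locus_info: pd.DataFrame) -> np.ndarray:
    sizes = locus_info.groupby("scaffold", sort=False).size().to_numpy()
    return np.concatenate([[0], np.cumsum(sizes)])


def simulate_progeny(panel: HaplotypePanel, config: SimConfig):
    """Drop open-pollinated half-sib progeny from the founder panel.

    Each mother is a distinct random founder-haplotype pair. Every offspring
    receives one recombinant maternal gamete and one recombinant gamete from
    an unrecorded founder father drawn uniformly from the panel (open
    pollination). Phase of the two gametes is retained.

    Returns ``(phase, pedigree)`` where ``phase`` is an
    (n_progeny, n_loci, 2) uint8 array of alternative-allele indicators
    (maternal gamete first) and ``pedigree`` records tree and mother ids.
    """
    if panel.n_loci == 0:
        raise ValueError("empty haplotype panel")
    if 2 * config.n_mothers > panel.n_haplotypes:
        raise ValueError(
            f"{config.n_mothers} mothers need {2 * config.n_mothers} founder "
            f"haplotypes but only {panel.n_haplotypes} are available"
        )
    rng_mating = config.rng("mating")
    rng_rec = config.rng("recombination")
    bounds = _scaffold_bounds(panel.locus_info)

    mother_haps = rng_mating.choice(
        panel.n_haplotypes, size=(config.n_mothers, 2), replace=False
    )
    n = config.n_trees
    phase = np.empty((n, panel.n_loci, 2), dtype=np.uint8)
    tree_ids, mother_ids = [], []
    i = 0
    for b in range(config.n_blocks):
        for mom in range(config.n_mothers):
            ma, mb = mother_haps[mom]
            for _ in range(config.progeny_per_family_per_block):
                phase[i, :, 0] = _recombine(
                    rng_rec, panel.alleles[ma], panel.alleles[mb], bounds
                )
                fa, fb = rng_mating.choice(panel.n_haplotypes, size=2, replace=False)
                phase[i, :, 1] = _recombine(
                    rng_rec, panel.alleles[fa], panel.alleles[fb], bounds
                )
                tree_ids.append(f"tree_{i + 1:05d}")
                mother_ids.append(f"mother_{mom + 1:03d}")
                i += 1
    pedigree = pd.DataFrame({"tree_id": tree_ids, "mother_id": mother_ids})
    return phase, pedigree


def codes_from_phase(phase: np.ndarray) -> np.ndarray:
    """Collapse a phase layer to -1/0/1 genotype codes (alt-allele dosage - 1)."""
    return phase.sum(axis=2).astype(np.int8) - 1


# The bimodal mode concentrates most of the additive budget on one major
# QTL of modest MAF: the common-homozygote and heterozygote classes then
# form two separated phenotype modes (a rarer allele keeps the third class
# negligible, which an intermediate-frequency QTL would not).
_BIMODAL_QTL_SHARE = 0.8
_BIMODAL_MAF_WINDOW = (0.08, 0.2)


def simulate_trait(
    codes: np.ndarray, config: SimConfig, panel: HaplotypePanel | None = None
):
    """Assign a genetic architecture and compute true genetic values.

    Genetic value = Σ additive effects on the -1/0/1 codes plus Σ pairwise
    code products for epistatic pairs. Components are centred and rescaled
    so their realized population variance fractions equal ``h2_additive``
    and ``h2_epistatic`` on a total-phenotypic-variance scale of 1.

    With ``bimodal_major_qtl`` one intermediate-frequency QTL receives a
    fixed large share of the additive budget, producing a bimodal phenotype
    distribution; visible bimodality requires a generous ``h2_additive``.
    """
    n, m = codes.shape
    if config.n_qtl_additive > m:
        raise ValueError("n_qtl_additive exceeds number of loci")
    poly = codes.std(axis=0) > 0
    if not poly.any():
        raise ValueError("no polymorphic locus")
    rng = config.rng("trait")
    candidates = np.nonzero(poly)[0]

    add_idx = rng.choice(candidates, size=min(config.n_qtl_additive, len(candidates)),
                         replace=False)
    add_eff = rng.normal(size=len(add_idx))

    if config.bimodal_major_qtl and len(add_idx) > 0:
        freq = (codes[:, candidates].mean(axis=0) + 1) / 2
        maf = np.minimum(freq, 1 - freq)
        window = np.nonzero((maf >= _BIMODAL_MAF_WINDOW[0]) & (maf <= _BIMODAL_MAF_WINDOW[1]))[0]
        pool = candidates[window] if len(window) else candidates
        major = rng.choice(pool)
        if major not in add_idx:
            add_idx[0] = major
        j = int(np.nonzero(add_idx == major)[0][0])
        x = codes[:, major].astype(float)
        others = np.delete(np.arange(len(add_idx)), j)
        a_minor = codes[:, add_idx[others]].astype(float) @ add_eff[others]
        v_minor = a_minor.var()
        target_major = _BIMODAL_QTL_SHARE * config.h2_additive
        target_minor = (1 - _BIMODAL_QTL_SHARE) * config.h2_additive
        if v_minor > 0:
            add_eff[others] *= np.sqrt(target_minor / v_minor)
        add_eff[j] = np.sqrt(target_major / max(x.var(), 1e-12)) * np.sign(rng.normal() or 1.0)
        additive = codes[:, add_idx].astype(float) @ add_eff
    else:
        additive = codes[:, add_idx].astype(float) @ add_eff
        v = additive.var()
        if config.h2_additive > 0 and v > 0:
            add_eff *= np.sqrt(config.h2_additive / v)
            additive = codes[:, add_idx].astype(float) @ add_eff
        elif config.h2_additive == 0:
            add_eff[:] = 0.0
            additive = np.zeros(n)

    if config.h2_epistatic > 0 and config.n_qtl_epistatic_pairs > 0:
        pairs = rng.choice(candidates, size=(config.n_qtl_epistatic_pairs, 2))
        epi_eff = rng.normal(size=config.n_qtl_epistatic_pairs)
        prod = codes[:, pairs[:, 0]].astype(float) * codes[:, pairs[:, 1]].astype(float)
        epi = prod @ epi_eff
        v = epi.var()
        if v > 0:
            epi_eff *= np.sqrt(config.h2_epistatic / v)
            epi = prod @ epi_eff
    else:
        pairs = np.empty((0, 2), dtype=int)
        epi_eff = np.empty(0)
        epi = np.zeros(n)

    resid_var = 1.0 - config.h2_additive - config.h2_epistatic - config.spatial_variance_fraction
    arch = TraitArchitecture(
        additive_qtl=add_idx,
        additive_effects=add_eff,
        epistatic_pairs=pairs,
        epistatic_effects=epi_eff,
        intercept=0.0,
        residual_sd=float(np.sqrt(resid_var)),
    )
    genetic = arch.intercept + (additive - additive.mean()) + (epi - epi.mean())
    return arch, genetic


def _cosine_surface(rng: np.random.Generator, x: np.ndarray, y: np.ndarray,
                    n_components: int = 6) -> np.ndarray:
    """Smooth low-frequency field surface: a few random 2-D cosine waves."""
    ext_x = max(x.max() - x.min(), 1.0)
    ext_y = max(y.max() - y.min(), 1.0)
    s = np.zeros_like(x, dtype=float)
    for _ in range(n_components):
        fx = rng.uniform(0.2, 1.5) / ext_x
        fy = rng.uniform(0.2, 1.5) / ext_y
        phi = rng.uniform(0, 2 * np.pi)
        s += rng.normal() * np.cos(2 * np.pi * (fx * x + fy * y) + phi)
    return s


def simulate_field(
    genetic: np.ndarray,
    pedigree: pd.DataFrame,
    config: SimConfig,
    arch: TraitArchitecture | None = None,
    trait_name: str = "trait",
) -> pd.DataFrame:
    """Place trees on the RCBD grid and emit phenotypes.

    Families are randomized within each block; blocks are laid out as
    adjacent column strips. A smooth cosine surface carrying
    ``spatial_variance_fraction`` of phenotypic variance and iid residual
    noise are added to the genetic values, then ``phenotype_missing_rate``
    of trees lose their phenotype (thinning/mortality).
    """
    n = config.n_trees
    if len(genetic) != n or len(pedigree) != n:
        raise ValueError("genetic values / pedigree length does not match the design")
    per_block = config.n_mothers * config.progeny_per_family_per_block
    rows_b = int(np.ceil(np.sqrt(per_block)))
    cols_b = int(np.ceil(per_block / rows_b))
    if rows_b * cols_b < per_block:
        raise ValueError("block grid too small")
    rng = config.rng("field")

    row = np.empty(n, dtype=int)
    col = np.empty(n, dtype=int)
    block = np.empty(n, dtype=int)
    for b in range(config.n_blocks):
        sl = slice(b * per_block, (b + 1) * per_block)
        cells = rng.permutation(rows_b * cols_b)[:per_block]
        row[sl] = cells // cols_b
        col[sl] = cells % cols_b + b * cols_b
        block[sl] = b + 1

    x = col * config.col_spacing_m
    y = row * config.row_spacing_m
    if config.spatial_variance_fraction > 0:
        s = _cosine_surface(rng, x.astype(float), y.astype(float))
        s = (s - s.mean()) / s.std() * np.sqrt(config.spatial_variance_fraction)
    else:
        s = np.zeros(n)
    resid_sd = arch.residual_sd if arch is not None else np.sqrt(
        1.0 - config.h2_additive - config.h2_epistatic - config.spatial_variance_fraction
    )
    pheno = genetic + s + rng.normal(scale=resid_sd, size=n)

    missing = config.rng("missing").random(n) < config.phenotype_missing_rate
    pheno = np.where(missing, np.nan, pheno)

    return pd.DataFrame(
        {
            "tree_id": pedigree["tree_id"].to_numpy(),
            "mother_id": pedigree["mother_id"].to_numpy(),
            "block": block,
            "row": row,
            "col": col,
            "x": x,
            "y": y,
            trait_name: pheno,
            f"{trait_name}_true_genetic": genetic,
            f"{trait_name}_true_spatial": s,
        }
    )


def simulate_study(config: SimConfig, traits: dict[str, dict] | None = None):
    """End-to-end simulation of a two-trait study.

    By default produces a bimodal additive trait ``D7`` (stem diameter-like)
    and an epistatic trait ``H7`` (tree height-like) on shared genotypes.
    ``traits`` maps trait name to SimConfig field overrides (architecture
    fields only). Returns ``(phase, codes, pedigree, phenotypes, panel,
    architectures)``; the phenotype frame has one column block per trait.
    """
    if traits is None:
        traits = {
            "D7": {"h2_additive": 0.37, "h2_epistatic": 0.0, "bimodal_major_qtl": True},
            "H7": {"h2_additive": 0.05, "h2_epistatic": 0.31, "bimodal_major_qtl": False},
        }
    panel = simulate_founder_haplotypes(config)
    phase, pedigree = simulate_progeny(panel, config)
    codes = codes_from_phase(phase)
    pheno = None
    archs = {}
    for k, (name, overrides) in enumerate(traits.items()):
        cfg = SimConfig(**{**asdict(config), **overrides, "seed": config.seed + 7919 * (k + 1)})
        arch, genetic = simulate_trait(codes, cfg, panel)
        tab = simulate_field(genetic, pedigree, cfg, arch, trait_name=name)
        arch.spatial_surface = tab[f"{name}_true_spatial"].to_numpy()
        archs[name] = arch
        if pheno is None:
            pheno = tab
        else:
            pheno = pheno.join(tab[[name, f"{name}_true_genetic", f"{name}_true_spatial"]])
    return phase, codes, pedigree, pheno, panel, archs


def write_fixture(
    phase: np.ndarray,
    locus_info: pd.DataFrame,
    phenotypes: pd.DataFrame,
    path: str | Path,
    config: SimConfig | None = None,
) -> dict[str, Path]:
    """Write a VCF (phased GTs) + phenotype TSV + JSON manifest fixture.

    Round-trips losslessly through :func:`gstrial.qc.read_vcf`. The manifest
    records the config and seed so the fixture can be regenerated
    byte-identically.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n, m, _ = phase.shape
    ids = phenotypes["tree_id"].to_numpy()
    if len(ids) != n:
        raise ValueError("phenotype rows do not match genotype samples")
    if len(locus_info) != m:
        raise ValueError("locus_info does not match genotype loci")

    vcf_path = path / "genotypes.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for scaf, sub in locus_info.groupby("scaffold", sort=False):
            fh.write(f"##contig=<ID={scaf}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ids) + "\n")
        scafs = locus_info["scaffold"].to_numpy()
        poss = locus_info["pos"].to_numpy()
        for j in range(m):
            gts = [f"{phase[i, j, 0]}|{phase[i, j, 1]}" for i in range(n)]
            fh.write(
                f"{scafs[j]}\t{poss[j]}\tsnp_{j + 1}\tA\tG\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )

    pheno_path = path / "phenotypes.tsv"
    phenotypes.to_csv(pheno_path, sep="\t", index=False, na_rep="NA")

    manifest_path = path / "manifest.json"
    digest = hashlib.sha256(vcf_path.read_bytes()).hexdigest()
    manifest = {
        "vcf": vcf_path.name,
        "phenotypes": pheno_path.name,
        "vcf_sha256": digest,
        "config": asdict(config) if config is not None else None,
        "seed": config.seed if config is not None else None,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return {"vcf": vcf_path, "phenotypes": pheno_path, "manifest": manifest_path}
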