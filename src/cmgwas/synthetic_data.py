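"""Synthetic genotype/phenotype generator with planted pleiotropic QTL.

The generator mirrors the generative assumptions of the association model:

    y_t = sum_q beta_qt * s_q + Q q_t + g_t + e_t

with a polygenic term g drawn with covariance proportional to the *realized*
genomic relationship matrix (so variance-component recovery is internally
consistent), a strain random effect through an admixture-style Q matrix, and
residuals correlated across traits.

Genotypes are built from a haplotype block model rather than a coalescent
simulation: it gives direct, testable control over the r² structure that the
stepwise conditional selection logic depends on. Within a block all variants
share one allele frequency and haplotype alleles come from thresholding a
latent Gaussian AR(1) chain with lag-1 correlation rho = 1 − 2·switch_prob:
switch_prob = 0 makes within-block columns identical (r² = 1), 0.5 makes
adjacent variants independent. Blocks are independent of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (GenotypeMatrix, GeneSet, PhenotypeTable, StrainMatrix,
                         ValidationError, variant_key)

_REF, _ALT = "A", "G"


def chrom_label(c: int) -> str:
    return f"chr{c + 1}"


def qtl_key(chrom_index: int, variant_index: int, spacing: int) -> str:
    """Deterministic key of the variant at a given within-chromosome index."""
    return variant_key(chrom_label(chrom_index), (variant_index + 1) * spacing,
                       _REF, _ALT)


@dataclass
class QTLSpec:
    """A planted causal variant: where it sits and what it does.

    ``effects`` are per-trait allele-substitution effects in phenotypic-SD
    units (per copy of the alternative allele), so a QTL explains about
    2·maf·(1−maf)·beta² of the phenotypic variance of each trait.
    Mixed-sign effect vectors give the pleiotropy patterns the multi-trait
    statistic is designed to pick up.
    """

    chrom: int                  # 0-based chromosome index
    index: int                  # 0-based variant index within the chromosome
    maf: float
    effects: np.ndarray         # length n_traits, SD units

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)


@dataclass
class SimConfig:
    """Study-design parameters for one simulated dataset.

    Defaults describe the canonical test condition used throughout the
    package: a multi-chromosome genome with LD blocks, 16 correlated traits
    with moderate heritability, three ancestral strains, and no QTL (add
    ``qtls`` to plant signal).
    """

    n_animals: int = 1000
    n_chromosomes: int = 5
    variants_per_chromosome: int = 1000
    block_len_mean: float = 20.0       # mean variants per LD block (1 = no LD)
    switch_prob: float = 0.02          # 0 = perfect copy, 0.5 = independent
    maf_min: float = 0.01
    maf_shape: float = 1.0             # >1 skews the MAF spectrum rarer
    n_traits: int = 16
    heritability: float | Sequence[float] = 0.4
    residual_corr: np.ndarray | None = None   # default: block-structured
    qtls: list[QTLSpec] = field(default_factory=list)
    n_strains: int = 3
    strain_var: float = 0.05           # sigma_q^2 analogue
    missing_rates: float | Sequence[float] = 0.0
    variant_spacing: int = 1000        # bp between adjacent variants
    seed: int = 0

    def h2_vector(self) -> np.ndarray:
        h2 = np.broadcast_to(np.asarray(self.heritability, float),
                             (self.n_traits,)).copy()
        if np.any(h2 < 0) or np.any(h2 >= 1):
            raise ValidationError("heritabilities must lie in [0, 1)")
        return h2

    def missing_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.missing_rates, float),
                               (self.n_traits,)).copy()

    def residual_corr_matrix(self) -> np.ndarray:
        R = (default_residual_corr(self.n_traits)
             if self.residual_corr is None else np.asarray(self.residual_corr, float))
        if R.shape != (self.n_traits, self.n_traits):
            raise ValidationError("residual correlation matrix has wrong shape")
        if not np.allclose(R, R.T):
            raise ValidationError("residual correlation matrix not symmetric")
        if np.min(np.linalg.eigvalsh(R)) <= 0:
            raise ValidationError("residual correlation matrix not positive definite")
        return R

    def validate(self) -> None:
        if self.block_len_mean < 1:
            raise ValidationError("block_len_mean must be ≥ 1")
        if not 0 <= self.switch_prob <= 0.5:
            raise ValidationError("switch_prob must lie in [0, 0.5]")
        if not 0 < self.maf_min < 0.5:
            raise ValidationError("maf_min must lie in (0, 0.5)")
        seen = set()
        for q in self.qtls:
            if not (0 <= q.chrom < self.n_chromosomes
                    and 0 <= q.index < self.variants_per_chromosome):
                raise ValidationError(f"QTL outside the simulated genome: {q}")
            if (q.chrom, q.index) in seen:
                raise ValidationError("duplicate QTL position")
            seen.add((q.chrom, q.index))
            if q.effects.shape != (self.n_traits,):
                raise ValidationError("QTL effect vector length != n_traits")
            if not self.maf_min <= q.maf <= 0.5:
                raise ValidationError("QTL MAF outside [maf_min, 0.5]")
        if len(self.qtls) > self.n_chromosomes * self.variants_per_chromosome:
            raise ValidationError("more QTL than variants")
        self.h2_vector()
        m = self.missing_vector()
        if np.any(m < 0) or np.any(m >= 1):
            raise ValidationError("missing rates must lie in [0, 1)")
        h2 = self.h2_vector()
        if np.any(h2 + self.strain_var >= 1):
            raise ValidationError("h2 + strain_var must stay below 1")

    def qtl_keys(self) -> list[str]:
        return [qtl_key(q.chrom, q.index, self.variant_spacing)
                for q in self.qtls]


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset, for recovery testing."""

    qtl_keys: list[str]
    effects: np.ndarray        # n_qtl × n_traits, SD units
    sigma_g2: np.ndarray       # per trait
    sigma_q2: float
    sigma_e2: np.ndarray       # per trait


def default_residual_corr(n_traits: int) -> np.ndarray:
    """Block-structured residual correlations: consecutive trait pairs
    (yearling/adult measurements of the same character) at 0.5, a common
    background of 0.2 elsewhere."""
    R = np.full((n_traits, n_traits), 0.2)
    for i in range(0, n_traits - 1, 2):
        R[i, i + 1] = R[i + 1, i] = 0.5
    np.fill_diagonal(R, 1.0)
    return R


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _draw_block_freq(rng: np.random.Generator, maf_min: float,
                     shape: float) -> float:
    """Log-uniform-style MAF spectrum on [maf_min, 0.5]; ``shape`` > 1 pushes
    mass toward rare variants. The minor allele is the alt allele half the
    time."""
    u = rng.random() ** shape
    maf = maf_min * (0.5 / maf_min) ** u
    return maf if rng.random() < 0.5 else 1.0 - maf


def _block_haplotypes(rng: np.random.Generator, n_hap: int, length: int,
                      freq: float, rho: float) -> np.ndarray:
    """0/1 haplotype alleles for one block: latent Gaussian AR(1) thresholded
    at the alt-allele frequency quantile."""
    z = np.empty((n_hap, length))
    z[:, 0] = rng.standard_normal(n_hap)
    if length > 1:
        innov = rng.standard_normal((n_hap, length - 1)) * np.sqrt(1 - rho ** 2)
        for j in range(1, length):
            z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
    tau = stats.norm.ppf(freq)
    return (z < tau).astype(np.int8)


def simulate_genotypes(config: SimConfig,
                       rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Sample block-structured dosages; variants whose realized MAF falls
    below ``config.maf_min`` are dropped (QTL-carrying blocks are redrawn
    instead, so every planted QTL survives)."""
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_hap = 2 * config.n_animals
    rho = 1.0 - 2.0 * config.switch_prob
    qtl_by_chrom: dict[int, set[int]] = {}
    for q in config.qtls:
        qtl_by_chrom.setdefault(q.chrom, set()).add(q.index)
    qtl_maf = {(q.chrom, q.index): q.maf for q in config.qtls}

    all_cols, all_meta = [], []
    for c in range(config.n_chromosomes):
        m_c = config.variants_per_chromosome
        start = 0
        while start < m_c:
            if config.block_len_mean <= 1:
                length = 1
            else:
                length = 1 + rng.poisson(config.block_len_mean - 1)
            length = min(length, m_c - start)
            block_idx = range(start, start + length)
            block_qtl = [i for i in block_idx if i in qtl_by_chrom.get(c, ())]
            for attempt in range(200):
                if block_qtl:
                    freq = qtl_maf[(c, block_qtl[0])]  # alt allele = minor
                else:
                    freq = _draw_block_freq(rng, config.maf_min, config.maf_shape)
                hap = _block_haplotypes(rng, n_hap, length, freq, rho)
                dos = (hap[:config.n_animals] + hap[config.n_animals:]).astype(float)
                f = dos.mean(axis=0) / 2.0
                maf = np.minimum(f, 1 - f)
                if not block_qtl:
                    break
                if np.all(maf[[i - start for i in block_qtl]] >= config.maf_min):
                    break
            else:
                raise ValidationError(
                    f"could not realize MAF ≥ {config.maf_min} for QTL block "
                    f"on {chrom_label(c)}")
            keep = maf >= config.maf_min
            for i in block_qtl:
                keep[i - start] = True
            for j, i in enumerate(block_idx):
                if keep[j]:
                    all_cols.append(dos[:, j])
                    all_meta.append((chrom_label(c),
                                     (i + 1) * config.variant_spacing,
                                     _REF, _ALT))
            start += length

    vm = pd.DataFrame(all_meta, columns=["chrom", "pos", "ref", "alt"])
    vm["id"] = [variant_key(*m) for m in all_meta]
    ids = [f"an{i:05d}" for i in range(config.n_animals)]
    return GenotypeMatrix(np.column_stack(all_cols), vm, ids)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def simulate_traits(genotypes: GenotypeMatrix, config: SimConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[PhenotypeTable, StrainMatrix, SimTruth]:
    """Phenotypes on top of given genotypes: planted QTL + strain effect +
    GRM-distributed polygenic term + correlated residuals, with per-trait
    missing-completely-at-random records.

    Variance bookkeeping (per trait, phenotypic SD units of the QTL-free
    baseline): polygenic sigma_g² = h², strain sigma_q² = ``strain_var``,
    residual sigma_e² = 1 − h² − sigma_q²; QTL variance comes on top.
    """
    config.validate()
    rng = (np.random.default_rng([config.seed, 1]) if rng is None else rng)
    n, T = genotypes.n_animals, config.n_traits
    h2 = config.h2_vector()
    sigma_e2 = 1.0 - h2 - config.strain_var
    R = config.residual_corr_matrix()

    key_to_col = genotypes.key_index()
    keys = config.qtl_keys()
    missing = [k for k in keys if k not in key_to_col]
    if missing:
        raise ValidationError(f"QTL variants absent from genotypes: {missing}")

    y = np.zeros((n, T))
    effects = np.zeros((len(keys), T))
    for qi, (q, k) in enumerate(zip(config.qtls, keys)):
        s = genotypes.dosages[:, key_to_col[k]]
        y += np.outer(s, q.effects)
        effects[qi] = q.effects

    # strain structure: sparse admixture proportions
    Q = rng.dirichlet(np.full(config.n_strains, 0.5), size=n)
    q_eff = rng.standard_normal((config.n_strains, T)) * np.sqrt(config.strain_var)
    y += Q @ q_eff

    # polygenic term with covariance equal to the realized GRM: with
    # W the centred/scaled dosage matrix, W u/sqrt(m) has covariance
    # W Wᵀ/m = G exactly, so no explicit GRM or factorization is needed
    if np.any(h2 > 0):
        from .grm_ld import allele_freq

        af = allele_freq(genotypes)
        poly = (af.freq > 0) & (af.freq < 1)
        p = af.freq[poly]
        W = (genotypes.dosages[:, poly] - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
        m = W.shape[1]
        g = (W @ rng.standard_normal((m, T))) / np.sqrt(m)
        y += g * np.sqrt(h2)

    # correlated residuals
    Lr = np.linalg.cholesky(R)
    e = rng.standard_normal((n, T)) @ Lr.T
    y += e * np.sqrt(sigma_e2)

    for t, rate in enumerate(config.missing_vector()):
        if rate > 0:
            y[rng.random(n) < rate, t] = np.nan

    trait_names = [f"trait{t + 1:02d}" for t in range(T)]
    phen = PhenotypeTable(y, trait_names, list(genotypes.animal_ids))
    strains = StrainMatrix(Q, [f"strain{s + 1}" for s in range(config.n_strains)],
                           list(genotypes.animal_ids))
    truth = SimTruth(keys, effects, h2.copy(), config.strain_var, sigma_e2)
    return phen, strains, truth


def simulate_dataset(config: SimConfig):
    """Convenience: genotypes + phenotypes + strains + truth from one config."""
    gm = simulate_genotypes(config)
    phen, strains, truth = simulate_traits(gm, config)
    return gm, phen, strains, truth


# ---------------------------------------------------------------------------
# Genes
# ---------------------------------------------------------------------------

def simulate_genes(genotypes: GenotypeMatrix, density: float, seed: int = 0,
                   qtl_positions: Sequence[tuple[str, int]] = ()) -> GeneSet:
    """Random gene intervals at ``density`` genes per Mb.

    If QTL positions are supplied, each gets one overlapping gene and (when
    the chromosome is long enough) one gene beyond 100 kb, so annotation
    behaviour is testable at both ends of the window.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, sub in genotypes.variant_meta.groupby("chrom", sort=False):
        length = int(sub["pos"].max()) + 1000
        n_genes = rng.poisson(density * length / 1e6)
        for i in range(n_genes):
            glen = int(rng.integers(2_000, 20_000))
            start = int(rng.integers(1, max(2, length - glen)))
            rows.append((chrom, start, start + glen - 1,
                         f"G{chrom.upper()}_{i + 1}", "+" if rng.random() < 0.5 else "-"))
    for j, (chrom, pos) in enumerate(qtl_positions):
        rows.append((chrom, max(1, pos - 500), pos + 500, f"QGENE_{j + 1}", "+"))
        length = int(genotypes.variant_meta.loc[
            genotypes.variant_meta["chrom"] == chrom, "pos"].max()) + 1000
        far_start = pos + 150_000
        if far_start + 5_000 < length + 200_000:
            rows.append((chrom, far_start, far_start + 5_000,
                         f"FARGENE_{j + 1}", "-"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return GeneSet(df)
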