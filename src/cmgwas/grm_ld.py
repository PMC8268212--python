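"""Allele frequencies, the genomic relationship matrix, and pairwise LD r².

GRM construction follows the VanRaden method-1 centred-and-scaled
cross-product: W_ij = (d_ij − 2p_j)/sqrt(2 p_j (1 − p_j)), G = W Wᵀ / m over
the m variants passing the MAF filter (default MAF > 0.005). Missing dosages
are mean-imputed for the GRM and pairwise-deleted for LD — the data are
assumed to be imputed anyway, so both choices are essentially no-ops in
practice.

r² is the squared Pearson correlation of dosage vectors (the PLINK ``--r2``
genotype-count convention on unphased data), not a haplotype D′ estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import GenotypeMatrix, ValidationError

logger = logging.getLogger("cmgwas")


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFreqs:
    freq: np.ndarray        # alt-allele frequency, nan when all missing
    maf: np.ndarray
    n_called: np.ndarray    # non-missing genotypes per variant

    @property
    def all_missing(self) -> np.ndarray:
        return self.n_called == 0


def allele_freq(genotypes: GenotypeMatrix) -> AlleleFreqs:
    """Alt-allele frequency (mean dosage / 2 over non-missing entries) and
    the minor-allele frequency per variant. Variants with every entry
    missing are flagged (``freq`` = nan) and must be excluded downstream."""
    if genotypes.n_animals < 1:
        raise ValidationError("need at least one animal")
    d = genotypes.dosages
    called = ~np.isnan(d)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(d, axis=0) / (2.0 * n_called)
    freq[n_called == 0] = np.nan
    maf = np.minimum(freq, 1.0 - freq)
    if np.any(n_called == 0):
        logger.warning("%d variants have no called genotypes",
                       int(np.sum(n_called == 0)))
    return AlleleFreqs(freq, maf, n_called)


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

@dataclass
class GRM:
    """Genomic relationship matrix with its provenance."""

    matrix: np.ndarray
    animal_ids: list[str]
    variant_keys: list[str]     # variants actually used
    maf_threshold: float

    @property
    def n_animals(self) -> int:
        return self.matrix.shape[0]

    def subset(self, rows: np.ndarray) -> np.ndarray:
        """Dense submatrix for a boolean or index row selector."""
        sub = self.matrix[rows][:, rows]
        return np.ascontiguousarray(sub)


def build_grm(genotypes: GenotypeMatrix, maf_threshold: float = 0.005) -> GRM:
    """VanRaden method-1 GRM over variants with MAF strictly above the
    threshold (matching the source rule "MAF had to be higher than 0.005")."""
    if genotypes.n_animals < 2:
        raise ValidationError("GRM needs at least two animals")
    af = allele_freq(genotypes)
    keep = np.where(~np.isnan(af.maf) & (af.maf > maf_threshold))[0]
    if keep.size == 0:
        raise ValidationError(
            f"no variant passes MAF > {maf_threshold}; cannot build a GRM")
    d = genotypes.dosages[:, keep]
    p = af.freq[keep]
    # mean-impute missing entries at 2p (zero after centring)
    d = np.where(np.isnan(d), 2.0 * p, d)
    W = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    G = (W @ W.T) / keep.size
    keys = genotypes.variant_keys()
    return GRM(G, list(genotypes.animal_ids), [keys[j] for j in keep],
               maf_threshold)


def write_grm(grm: GRM, path) -> None:
    import pandas as pd

    df = pd.DataFrame(grm.matrix, columns=grm.animal_ids)
    df.insert(0, "animal_id", grm.animal_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_grm(path) -> GRM:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={0: str})
    ids = df.iloc[:, 0].tolist()
    return GRM(df.iloc[:, 1:].to_numpy(float), ids, [], float("nan"))


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

@dataclass
class LDResult:
    """r² of candidate variants against one anchor variant."""

    anchor: str
    keys: list[str]
    r2: np.ndarray
    undefined: np.ndarray   # True where either vector had zero variance

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.keys, self.r2))


def _pairwise_r2(a: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Squared Pearson correlation of ``a`` against each column of ``C``
    with pairwise deletion of missing entries. Undefined correlations
    (zero variance over the joint rows) come back as nan."""
    va = ~np.isnan(a)
    Mc = ~np.isnan(C)
    both = va[:, None] & Mc
    n = both.sum(axis=0).astype(float)
    a0 = np.where(va, a, 0.0)
    C0 = np.where(Mc, C, 0.0)
    sa = a0 @ both
    sc = (C0 * both).sum(axis=0)
    saa = (a0 ** 2) @ both
    scc = (C0 ** 2 * both).sum(axis=0)
    sac = a0 @ C0  # a0 zero outside va; C0 zero outside Mc → joint rows only
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sac - sa * sc / n
        var_a = saa - sa ** 2 / n
        var_c = scc - sc ** 2 / n
        r2 = cov ** 2 / (var_a * var_c)
    undefined = (n < 2) | (var_a <= 0) | (var_c <= 0)
    r2[undefined] = np.nan
    return np.clip(r2, 0.0, 1.0, out=r2), undefined


def ld_r2(genotypes: GenotypeMatrix, a: str, b: str) -> float:
    """r² between two variants; nan signals undefined LD (zero variance),
    which callers treat as r² = 0."""
    idx = genotypes.key_index()
    for k in (a, b):
        if k not in idx:
            raise ValidationError(f"unknown variant {k}")
    r2, undef = _pairwise_r2(genotypes.dosages[:, idx[a]],
                             genotypes.dosages[:, [idx[b]]])
    if undef[0]:
        logger.warning("undefined LD for pair (%s, %s): zero dosage variance", a, b)
        return float("nan")
    return float(r2[0])


def ld_scan(genotypes: GenotypeMatrix, anchor: str,
            candidates: list[str]) -> LDResult:
    """r² of every candidate against the anchor. All candidates must share
    the anchor's chromosome; undefined pairs are reported as r² = 0 with the
    ``undefined`` flag set."""
    idx = genotypes.key_index()
    if anchor not in idx:
        raise ValidationError(f"unknown anchor variant {anchor}")
    chroms = genotypes.chrom_of()
    a_chrom = chroms[idx[anchor]]
    cols = []
    for k in candidates:
        if k not in idx:
            raise ValidationError(f"unknown variant {k}")
        if chroms[idx[k]] != a_chrom:
            raise ValidationError(
                f"candidate {k} is not on the anchor's chromosome {a_chrom}")
        cols.append(idx[k])
    if not cols:
        return LDResult(anchor, [], np.empty(0), np.empty(0, dtype=bool))
    r2, undef = _pairwise_r2(genotypes.dosages[:, idx[anchor]],
                             genotypes.dosages[:, cols])
    if np.any(undef):
        logger.warning("%d undefined-LD pairs against %s treated as r²=0",
                       int(undef.sum()), anchor)
        r2 = np.where(undef, 0.0, r2)
    return LDResult(anchor, list(candidates), r2, undef)
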