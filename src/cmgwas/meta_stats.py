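"""Multi-trait meta-analysis statistic, FDR estimator and inflation
diagnostics.

The multi-trait statistic combines the per-variant vector of signed t-values
t_i across traits through the inverse of the trait-by-trait correlation
matrix V of those t-values:

    multi-trait chi² = t_iᵀ V⁻¹ t_i,   df = number of traits.

V is estimated over *all* scanned variants (not only significant ones) as
pairwise Pearson correlations, with an eigenvalue floor applied before
inversion when a pair of traits is (near-)degenerate.

FDR uses the closed-form count estimator

    FDR = P (1 − A/T) / ((A/T) (1 − P)),

with P the threshold, A the number of significant tests and T the number of
tests; A = 0 leaves it undefined (reported as not available), and values
above 1 are reported as > 100 %.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ValidationError
from .mlm_engine import AssocTable

logger = logging.getLogger("cmgwas")

MIN_SHARED_VARIANTS = 100
EIGEN_FLOOR = 1e-6

# median of the 1-df chi-squared distribution; reference point of the
# median-based genomic inflation factor
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class TraitCorr:
    """Trait-by-trait correlation matrix V of signed t-values."""

    V: np.ndarray
    Vinv: np.ndarray
    trait_names: list[str]
    n_variants: int
    floored: bool = False

    @property
    def n_traits(self) -> int:
        return self.V.shape[0]


@dataclass
class MetaResult:
    """Per-variant multi-trait chi² and P (df = number of traits)."""

    variant_keys: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    chisq: np.ndarray
    p: np.ndarray
    df: int
    undefined: np.ndarray    # True where every trait entry was missing

    def significant(self, p_threshold: float) -> np.ndarray:
        return (~self.undefined) & (self.p < p_threshold)


def trait_corr(assoc: AssocTable, min_shared: int = MIN_SHARED_VARIANTS,
               eigen_floor: float = EIGEN_FLOOR) -> TraitCorr:
    """Pairwise Pearson correlation of signed t-values over variants where
    both traits are defined; floored and re-normalized if not positive
    definite, then inverted."""
    T = len(assoc.trait_names)
    if T < 2:
        raise ValidationError("trait correlation needs ≥ 2 traits")
    tm = assoc.t
    defined = ~np.isnan(tm)
    V = np.eye(T)
    for i in range(T):
        for j in range(i + 1, T):
            both = defined[:, i] & defined[:, j]
            n = int(both.sum())
            if n < min_shared:
                raise ValidationError(
                    f"traits {assoc.trait_names[i]!r} and "
                    f"{assoc.trait_names[j]!r} share only {n} variants "
                    f"(< {min_shared})")
            x, y = tm[both, i], tm[both, j]
            V[i, j] = V[j, i] = float(np.corrcoef(x, y)[0, 1])
    w, U = np.linalg.eigh(V)
    floored = bool(w.min() < eigen_floor)
    if floored:
        logger.warning("trait correlation matrix floored: min eigenvalue "
                       "%.3g < %.1g", w.min(), eigen_floor)
        V = (U * np.maximum(w, eigen_floor)) @ U.T
        scale = np.sqrt(np.diag(V))
        V = V / np.outer(scale, scale)   # restore unit diagonal
    Vinv = np.linalg.inv(V)
    n_var = int(defined.all(axis=1).sum())
    return TraitCorr(V, 0.5 * (Vinv + Vinv.T), list(assoc.trait_names),
                     n_var, floored)


def multitrait_chisq(t: np.ndarray, V: TraitCorr | np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """chi² = tᵀ V⁻¹ t with df = n_traits, for one t vector or a matrix of
    them (variants × traits). Missing (nan) trait entries are set to 0 with
    V unchanged — conservative, it can only shrink chi². A variant with every
    entry missing is undefined (chi² = nan, P = nan)."""
    if isinstance(V, TraitCorr):
        Vinv = V.Vinv
        T = V.n_traits
    else:
        V = np.asarray(V, float)
        Vinv = np.linalg.inv(V)
        T = V.shape[0]
    t = np.asarray(t, float)
    single = t.ndim == 1
    tm = t[None, :] if single else t
    if tm.shape[1] != T:
        raise ValidationError("t vector length does not match trait count")
    all_missing = np.isnan(tm).all(axis=1)
    t0 = np.nan_to_num(tm, nan=0.0)
    chisq = np.einsum("ij,jk,ik->i", t0, Vinv, t0)
    chisq = np.clip(chisq, 0.0, None)
    p = stats.chi2.sf(chisq, T)
    # keep P in (0, 1]: extreme statistics underflow the survival function
    p = np.where(p == 0.0, np.nextafter(0.0, 1.0), p)
    chisq[all_missing] = np.nan
    p[all_missing] = np.nan
    if single:
        return float(chisq[0]), float(p[0])
    return chisq, p


def meta_analysis(assoc: AssocTable, corr: TraitCorr | None = None
                  ) -> tuple[MetaResult, TraitCorr]:
    """Convenience: trait correlation (unless given) + per-variant
    multi-trait chi²/P over an association table."""
    if corr is None:
        corr = trait_corr(assoc)
    chisq, p = multitrait_chisq(assoc.t, corr)
    undefined = np.isnan(assoc.t).all(axis=1)
    if undefined.any():
        logger.warning("%d variants untested in every trait", undefined.sum())
    res = MetaResult(list(assoc.variant_keys), assoc.chrom, assoc.pos,
                     chisq, p, corr.n_traits, undefined)
    return res, corr


def fdr(p_threshold: float, n_significant: int, n_tested: int) -> float:
    """Closed-form FDR from counts; nan when nothing is significant (not
    available), values above 1 mean an FDR above 100 %."""
    P, A, T = p_threshold, n_significant, n_tested
    if not 0 < P < 1:
        raise ValidationError("P threshold must lie in (0, 1)")
    if T <= 0:
        raise ValidationError("T must be positive")
    if A < 0 or A > T:
        raise ValidationError("need 0 ≤ A ≤ T")
    if A == 0:
        return float("nan")
    rate = A / T
    return float(P * (1.0 - rate) / (rate * (1.0 - P)))


def format_fdr_percent(value: float, decimals: int = 1) -> str:
    """Report-style rendering: percent to the given precision, ``NA`` when
    undefined, ``>100`` when the estimate exceeds 100 %."""
    if np.isnan(value):
        return "NA"
    if value > 1.0:
        return ">100"
    return f"{100.0 * value:.{decimals}f}"


def inflation_lambda(pvalues: np.ndarray) -> float:
    """Median-based genomic inflation factor with a 1-df chi² reference:
    lambda = median(chi²₁(P)) / median(chi²₁)."""
    p = np.asarray(pvalues, float)
    if p.size < 100:
        raise ValidationError("need ≥ 100 P-values for lambda")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("P-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_1DF_MEDIAN)


def qq_data(pvalues: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(expected, observed) −log10 P pairs, sorted ascending, for Q–Q plots."""
    p = np.asarray(pvalues, float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("P-values must lie in (0, 1]")
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)[::-1]
    observed = -np.log10(np.sort(p))[::-1]
    return expected, observed
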