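"""REML variance components and mixed-model association scans.

Model (per trait, phenotypes pre-adjusted for fixed effects):

    y = 1 mu + s_i alpha_i + Q q + g + e,
    q ~ N(0, I sigma_q²),  g ~ N(0, G sigma_g²),  e ~ N(0, I sigma_e²),

so var(y) = G sigma_g² + Q Qᵀ sigma_q² + I sigma_e². Variance components are
estimated once per trait by average-information REML (EM fallback,
non-negativity projection) *without* any SNP in the model, then held fixed;
each variant is tested one at a time by GLS under that covariance, optionally
jointly with a set of conditioning variants fitted as fixed covariates.

Numerics: for each missingness pattern the GRM submatrix is eigendecomposed
once, G = U D Uᵀ. In the rotated basis the covariance is diagonal plus a
rank-s strain term, Ṽ = (sigma_g² D + sigma_e² I) + sigma_q² Q̃ Q̃ᵀ, so every
REML iteration and every per-variant GLS solve costs O(n s²) via the
Woodbury identity instead of O(n³). This is algebraically exact, not an
approximation. P-values use the standard normal (Wald) reference; at the
sample sizes this tool targets the difference from a t reference is
negligible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, stats

from .grm_ld import GRM, allele_freq, build_grm
from .io_formats import (GenotypeMatrix, PhenotypeTable, StrainMatrix,
                         ValidationError)

logger = logging.getLogger("cmgwas")

REML_TOL = 1e-6
REML_MAX_ITER = 200
MIN_RECORDS = 30
COLLINEAR_REL_TOL = 1e-3     # skip test variant when residual SSQ/SSQ < this
                             # (equivalent to r² > 0.999 with the base design)

# skip codes in AssocTable.skip
SKIP_NONE, SKIP_MAF, SKIP_ZERO_VAR, SKIP_COLLINEAR, SKIP_CONDITIONING = 0, 1, 2, 3, 4


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_q2: float
    sigma_e2: float
    loglik: float
    n_used: int
    converged: bool
    n_iter: int
    boundary: tuple[str, ...] = ()

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma_g2, self.sigma_q2, self.sigma_e2])


@dataclass
class AssocTable:
    """Per-variant, per-trait mixed-model association results."""

    variant_keys: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    trait_names: list[str]
    effects: np.ndarray      # m × T, nan where skipped
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    skip: np.ndarray | None = None   # m × T int8 skip codes
    n_used: np.ndarray | None = None  # records per trait

    def __post_init__(self) -> None:
        m, T = len(self.variant_keys), len(self.trait_names)
        if self.effects.shape != (m, T):
            raise ValidationError("association matrix shape mismatch")
        if self.skip is None:
            self.skip = np.zeros((m, T), dtype=np.int8)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    def trait_index(self, name: str) -> int:
        return self.trait_names.index(name)


@dataclass
class ConditioningSet:
    """Ordered variants fitted jointly as fixed covariates, grouped per
    chromosome."""

    keys: list[str]
    by_chrom: dict[str, list[str]]

    @classmethod
    def from_keys(cls, keys: Sequence[str],
                  genotypes: GenotypeMatrix) -> "ConditioningSet":
        keys = list(keys)
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate keys in conditioning set")
        idx = genotypes.key_index()
        chroms = genotypes.chrom_of()
        by_chrom: dict[str, list[str]] = {}
        for k in keys:
            if k not in idx:
                raise ValidationError(f"conditioning variant {k} not in genotypes")
            by_chrom.setdefault(chroms[idx[k]], []).append(k)
        return cls(keys, by_chrom)

    @classmethod
    def empty(cls) -> "ConditioningSet":
        return cls([], {})


# ---------------------------------------------------------------------------
# Rotated-basis machinery
# ---------------------------------------------------------------------------

class _Pattern:
    """Eigen-rotated design for one set of phenotyped animals."""

    def __init__(self, grm: GRM, strains: StrainMatrix, mask: np.ndarray):
        self.mask = mask
        G = grm.subset(mask)
        d, U = np.linalg.eigh(G)
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.Qr = U.T @ strains.proportions[mask]
        self.xr = U.T @ np.ones(mask.sum())
        self.n = int(mask.sum())
        self._rotated_dosages: np.ndarray | None = None
        self.grm_identity_like = bool(np.ptp(self.d) < 1e-8 * max(1.0, self.d.mean()))

    def rotate(self, M: np.ndarray) -> np.ndarray:
        return self.U.T @ M

    def rotated_dosages(self, genotypes: GenotypeMatrix,
                        fill: np.ndarray) -> np.ndarray:
        """UᵀS for this pattern's animals (missing dosages mean-imputed with
        ``fill`` = 2p); cached."""
        if self._rotated_dosages is None:
            S = genotypes.dosages[self.mask]
            if np.isnan(S).any():
                S = np.where(np.isnan(S), fill, S)
            self._rotated_dosages = self.U.T @ S
        return self._rotated_dosages


class _Cov:
    """Woodbury form of Ṽ = diag(sigma_g² d + sigma_e²) + sigma_q² Q̃ Q̃ᵀ."""

    def __init__(self, d: np.ndarray, Qr: np.ndarray, theta: np.ndarray):
        sg2, sq2, se2 = theta
        self.delta = np.maximum(sg2 * d + se2, 1e-12)
        self.Qr = Qr
        s = Qr.shape[1]
        self.Bq = Qr / self.delta[:, None]              # Δ⁻¹Q̃
        C = Qr.T @ self.Bq                              # Q̃ᵀΔ⁻¹Q̃
        inner = np.eye(s) + sq2 * C
        self.M = sq2 * np.linalg.solve(inner, np.eye(s))
        self.M = 0.5 * (self.M + self.M.T)
        self.C = C
        sign, ldet_inner = np.linalg.slogdet(inner)
        self.logdet = float(np.sum(np.log(self.delta)) + ldet_inner)

    def solve(self, v: np.ndarray) -> np.ndarray:
        """Ṽ⁻¹ v for a vector or matrix of column vectors."""
        u = v / self.delta[:, None] if v.ndim == 2 else v / self.delta
        return u - self.Bq @ (self.M @ (self.Qr.T @ u))

    # traces of Ṽ⁻¹K for the three variance structures ---------------------
    def trace_vinv_diag(self, w: np.ndarray) -> float:
        """tr(Ṽ⁻¹ diag(w))."""
        first = float(np.sum(w / self.delta))
        Cw = self.Qr.T @ (self.Bq * (w / self.delta)[:, None])
        return first - float(np.trace(self.M @ Cw))

    def trace_vinv_qq(self) -> float:
        """tr(Ṽ⁻¹ Q̃Q̃ᵀ) = tr(C) − tr(M C C)."""
        return float(np.trace(self.C) - np.trace(self.M @ self.C @ self.C))


def _reml(zy: np.ndarray, pat: _Pattern, tol: float = REML_TOL,
          max_iter: int = REML_MAX_ITER) -> VarianceComponents:
    """AI-REML with EM fallback for theta = (sigma_g², sigma_q², sigma_e²)
    on an eigen-rotated trait vector zy = Uᵀ(y − missing-dropped)."""
    n = zy.size
    vy = float(np.var(zy) + 1e-12)
    floor = 1e-10 * vy
    theta = np.array([0.4, 0.1, 0.5]) * vy
    d, Qr, xr = pat.d, pat.Qr, pat.xr
    ones = np.ones(n)

    def evaluate(th):
        cov = _Cov(d, Qr, th)
        a = cov.solve(xr)
        c = float(xr @ a)
        Pz = cov.solve(zy) - a * float(a @ zy) / c
        yPy = float(zy @ Pz)
        ll = -0.5 * (cov.logdet + np.log(c) + yPy)
        return cov, a, c, Pz, ll

    cov, a, c, Pz, ll = evaluate(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # scores: -0.5 (tr(P K_i) - uᵀ K_i u), u = Py
        def tr_P(K_kind):
            if K_kind == "g":
                tv = cov.trace_vinv_diag(d)
                ka = d * a
            elif K_kind == "q":
                tv = cov.trace_vinv_qq()
                ka = Qr @ (Qr.T @ a)
            else:
                tv = cov.trace_vinv_diag(ones)
                ka = a
            return tv - float(a @ ka) / c

        Ku = [d * Pz, Qr @ (Qr.T @ Pz), Pz]
        uKu = [float(Pz @ v) for v in Ku]
        trP = [tr_P(k) for k in ("g", "q", "e")]
        score = -0.5 * (np.array(trP) - np.array(uKu))

        def P_apply(v):
            w = cov.solve(v)
            return w - a * float(a @ v) / c

        PKu = [P_apply(v) for v in Ku]
        AI = 0.5 * np.array([[float(Ku[i] @ PKu[j]) for j in range(3)]
                             for i in range(3)])
        free = theta > floor * 1.001
        free |= score > 0          # allow leaving the boundary
        step = np.zeros(3)
        try:
            sub = np.ix_(free, free)
            step[free] = np.linalg.solve(AI[sub], score[free])
        except np.linalg.LinAlgError:
            step[:] = np.nan
        accepted = False
        if np.all(np.isfinite(step)):
            scale = 1.0
            for _ in range(12):
                new = np.maximum(theta + scale * step, floor)
                try:
                    cov2, a2, c2, Pz2, ll2 = evaluate(new)
                except np.linalg.LinAlgError:
                    scale *= 0.5
                    continue
                if ll2 >= ll - 1e-10:
                    accepted = True
                    break
                scale *= 0.5
        if not accepted:
            # EM step: theta_i += theta_i² (uᵀK_i u − tr(P K_i)) / n
            new = np.maximum(
                theta + theta ** 2 * (np.array(uKu) - np.array(trP)) / n, floor)
            cov2, a2, c2, Pz2, ll2 = evaluate(new)
        rel = abs(ll2 - ll) / (1.0 + abs(ll))
        theta, cov, a, c, Pz, ll = new, cov2, a2, c2, Pz2, ll2
        if rel < tol:
            converged = True
            break

    boundary = []
    if pat.grm_identity_like:
        boundary.append("grm-identity: sigma_g2/sigma_e2 not separable")
    for name, val in zip(("sigma_g2", "sigma_q2", "sigma_e2"), theta):
        if val <= floor * 1.001:
            boundary.append(f"{name} at zero boundary")
    if not converged:
        logger.warning("REML did not converge in %d iterations (last ll %.6g)",
                       max_iter, ll)
    return VarianceComponents(float(theta[0]), float(theta[1]), float(theta[2]),
                              float(ll), n, converged, it, tuple(boundary))


def _gls_scan(cov: _Cov, zy: np.ndarray, X0r: np.ndarray, Sr: np.ndarray,
              raw_var: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """GLS effect and SE of each column of Sr added to the base design X0r
    under fixed covariance. Returns (alpha, se, skip_codes)."""
    m = Sr.shape[1]
    VinvX0 = cov.solve(X0r)
    F = X0r.T @ VinvX0
    Fc = linalg.cho_factor(F)
    Vinvz = cov.solve(zy)
    r0 = X0r.T @ Vinvz
    Finv_r0 = linalg.cho_solve(Fc, r0)

    VinvS = cov.solve(Sr)
    Gm = X0r.T @ VinvS                      # p × m
    h = np.einsum("ij,ij->j", Sr, VinvS)
    r = Sr.T @ Vinvz
    FinvG = linalg.cho_solve(Fc, Gm)
    hstar = h - np.einsum("ij,ij->j", Gm, FinvG)
    alpha = np.full(m, np.nan)
    se = np.full(m, np.nan)
    skip = np.zeros(m, dtype=np.int8)
    skip[raw_var <= 0] = SKIP_ZERO_VAR
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(h > 0, hstar / h, 0.0)
    collinear = (skip == SKIP_NONE) & (rel < COLLINEAR_REL_TOL)
    skip[collinear] = SKIP_COLLINEAR
    ok = skip == SKIP_NONE
    alpha[ok] = (r[ok] - Gm[:, ok].T @ Finv_r0) / hstar[ok]
    se[ok] = 1.0 / np.sqrt(hstar[ok])
    return alpha, se, skip


# ---------------------------------------------------------------------------
# Scanner: shared caches across traits / cycles
# ---------------------------------------------------------------------------

class MixedModelScanner:
    """Holds the aligned inputs plus per-missingness-pattern eigen caches so
    that conditional re-scans across CM-GWAS cycles cost only the GLS step."""

    def __init__(self, phenos: PhenotypeTable, genotypes: GenotypeMatrix,
                 strains: StrainMatrix, grm: GRM | None = None,
                 maf_threshold: float = 0.005):
        ids = genotypes.animal_ids
        if phenos.animal_ids != ids or strains.animal_ids != ids:
            raise ValidationError(
                "inputs must be aligned on the same animal ids "
                "(use io_formats.align_animals)")
        self.phenos = phenos
        self.genotypes = genotypes
        self.strains = strains
        self.grm = grm if grm is not None else build_grm(genotypes)
        self.maf_threshold = maf_threshold
        af = allele_freq(genotypes)
        self.freq = af.freq
        self.maf_pass = (~np.isnan(af.maf)) & (af.maf > maf_threshold)
        self.raw_var = np.nanvar(genotypes.dosages, axis=0)
        self.key_idx = genotypes.key_index()
        self.chroms = genotypes.chrom_of()
        self._patterns: dict[bytes, _Pattern] = {}
        self._vc: dict[int, VarianceComponents] = {}

    # -- pattern cache -----------------------------------------------------
    def _pattern_for(self, mask: np.ndarray) -> _Pattern:
        key = np.packbits(mask).tobytes()
        pat = self._patterns.get(key)
        if pat is None:
            pat = _Pattern(self.grm, self.strains, mask)
            self._patterns[key] = pat
        return pat

    def _trait_mask(self, t: int) -> np.ndarray:
        mask = ~np.isnan(self.phenos.values[:, t])
        if mask.sum() < MIN_RECORDS:
            raise ValidationError(
                f"trait {self.phenos.trait_names[t]!r} has "
                f"{int(mask.sum())} records; need ≥ {MIN_RECORDS}")
        return mask

    # -- variance components ----------------------------------------------
    def variance_components(self, t: int) -> VarianceComponents:
        vc = self._vc.get(t)
        if vc is None:
            mask = self._trait_mask(t)
            pat = self._pattern_for(mask)
            zy = pat.U.T @ self.phenos.values[mask, t]
            vc = _reml(zy, pat)
            self._vc[t] = vc
            logger.info("REML %s: sg2=%.4g sq2=%.4g se2=%.4g (%d iters, "
                        "converged=%s)", self.phenos.trait_names[t],
                        vc.sigma_g2, vc.sigma_q2, vc.sigma_e2, vc.n_iter,
                        vc.converged)
        return vc

    def set_variance_components(self, t: int, vc: VarianceComponents) -> None:
        self._vc[t] = vc

    # -- scans -------------------------------------------------------------
    def scan_trait(self, t: int, variant_cols: np.ndarray | None = None,
                   conditioning_keys: Sequence[str] = ()
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """GLS scan of one trait over ``variant_cols`` (default: all MAF-passing
        variants), conditioning on the given variants as fixed covariates.
        Returns (cols, alpha, se, skip) aligned with ``cols``."""
        mask = self._trait_mask(t)
        pat = self._pattern_for(mask)
        vc = self.variance_components(t)
        cov = _Cov(pat.d, pat.Qr, vc.as_array())
        zy = pat.U.T @ self.phenos.values[mask, t]

        if variant_cols is None:
            cols = np.where(self.maf_pass)[0]
        else:
            cols = np.asarray(variant_cols)
            cols = cols[self.maf_pass[cols]]
        fill = 2.0 * np.where(np.isnan(self.freq), 0.0, self.freq)
        Sr_all = pat.rotated_dosages(self.genotypes, fill)

        X0_parts = [pat.xr[:, None]]
        cond_cols = []
        for k in conditioning_keys:
            j = self.key_idx.get(k)
            if j is None:
                raise ValidationError(f"conditioning variant {k} not in genotypes")
            cond_cols.append(j)
            X0_parts.append(Sr_all[:, [j]])
        X0r = np.hstack(X0_parts)

        test_cols = cols[~np.isin(cols, cond_cols)] if cond_cols else cols
        alpha, se, skip = _gls_scan(cov, zy, X0r, Sr_all[:, test_cols],
                                    self.raw_var[test_cols])
        if cond_cols:
            # conditioning variants are not re-tested; caller carries their
            # original statistics forward
            extra = np.array([c for c in cols if c in cond_cols], dtype=int)
            cols_out = np.concatenate([test_cols, extra])
            alpha = np.concatenate([alpha, np.full(extra.size, np.nan)])
            se = np.concatenate([se, np.full(extra.size, np.nan)])
            skip = np.concatenate([skip,
                                   np.full(extra.size, SKIP_CONDITIONING,
                                           dtype=np.int8)])
            order = np.argsort(cols_out, kind="mergesort")
            return cols_out[order], alpha[order], se[order], skip[order]
        return test_cols, alpha, se, skip


# ---------------------------------------------------------------------------
# Public one-shot API
# ---------------------------------------------------------------------------

def estimate_vc(y: np.ndarray, strains: StrainMatrix, grm: GRM,
                tol: float = REML_TOL,
                max_iter: int = REML_MAX_ITER) -> VarianceComponents:
    """REML variance components (sigma_g², sigma_q², sigma_e²) for one trait.

    ``y`` is aligned with ``grm.animal_ids``; nan entries are dropped and the
    GRM/strain rows subset accordingly.
    """
    y = np.asarray(y, dtype=float)
    if y.size != grm.n_animals:
        raise ValidationError("phenotype vector does not match GRM animals")
    mask = ~np.isnan(y)
    if mask.sum() < MIN_RECORDS:
        raise ValidationError(f"need ≥ {MIN_RECORDS} non-missing records")
    pat = _Pattern(grm, strains, mask)
    zy = pat.U.T @ y[mask]
    return _reml(zy, pat, tol=tol, max_iter=max_iter)


def _assemble_assoc(genotypes: GenotypeMatrix, trait_names: list[str],
                    per_trait: list[tuple[np.ndarray, np.ndarray, np.ndarray,
                                          np.ndarray]],
                    n_used: np.ndarray) -> AssocTable:
    m = genotypes.n_variants
    T = len(trait_names)
    eff = np.full((m, T), np.nan)
    se = np.full((m, T), np.nan)
    skip = np.full((m, T), SKIP_MAF, dtype=np.int8)
    for t, (cols, a, s, sk) in enumerate(per_trait):
        eff[cols, t] = a
        se[cols, t] = s
        skip[cols, t] = sk
    with np.errstate(invalid="ignore", divide="ignore"):
        tval = eff / se
        pval = 2.0 * stats.norm.sf(np.abs(tval))
    return AssocTable(genotypes.variant_keys(), genotypes.chrom_of(),
                      genotypes.positions(), trait_names, eff, se, tval, pval,
                      skip=skip, n_used=n_used)


def gwas_scan(y: np.ndarray, strains: StrainMatrix, grm: GRM,
              genotypes: GenotypeMatrix, vc: VarianceComponents | None = None,
              conditioning: ConditioningSet | Sequence[str] | None = None,
              maf_threshold: float = 0.005,
              trait_name: str = "trait") -> AssocTable:
    """Single-trait mixed-model scan: each MAF-passing variant tested one at
    a time by GLS under the fixed covariance implied by ``vc`` (estimated
    here if not supplied), optionally conditioning on selected variants."""
    phen = PhenotypeTable(np.asarray(y, float)[:, None], [trait_name],
                          list(genotypes.animal_ids))
    scanner = MixedModelScanner(phen, genotypes, strains, grm, maf_threshold)
    if vc is not None:
        scanner.set_variance_components(0, vc)
    keys = (conditioning.keys if isinstance(conditioning, ConditioningSet)
            else list(conditioning or ()))
    res = scanner.scan_trait(0, conditioning_keys=keys)
    n_used = np.array([int(np.sum(~np.isnan(y)))])
    return _assemble_assoc(genotypes, [trait_name], [res], n_used)


def scan_all_traits(phenos: PhenotypeTable, genotypes: GenotypeMatrix,
                    strains: StrainMatrix, grm: GRM | None = None,
                    maf_threshold: float = 0.005,
                    conditioning_by_chrom: dict[str, Sequence[str]] | None = None,
                    scanner: MixedModelScanner | None = None) -> AssocTable:
    """Per-trait scans over all traits with per-trait record subsetting.

    With ``conditioning_by_chrom``, only variants on those chromosomes are
    re-tested conditionally; all other chromosomes get the unconditional
    scan (callers in the conditional loop cache those instead of re-running).
    """
    if scanner is None:
        scanner = MixedModelScanner(phenos, genotypes, strains, grm,
                                    maf_threshold)
    T = phenos.n_traits
    per_trait = []
    for t in range(T):
        if conditioning_by_chrom:
            parts = []
            for chrom, keys in conditioning_by_chrom.items():
                cols = np.where(scanner.chroms == chrom)[0]
                parts.append(scanner.scan_trait(t, cols, list(keys)))
            rest = np.where(~np.isin(scanner.chroms,
                                     list(conditioning_by_chrom)))[0]
            if rest.size:
                parts.append(scanner.scan_trait(t, rest))
            cols = np.concatenate([p[0] for p in parts])
            order = np.argsort(cols, kind="mergesort")
            per_trait.append(tuple(np.concatenate([p[i] for p in parts])[order]
                                   for i in range(4)))
        else:
            per_trait.append(scanner.scan_trait(t))
    n_used = np.sum(~np.isnan(phenos.values), axis=0)
    return _assemble_assoc(genotypes, list(phenos.trait_names), per_trait,
                           n_used)
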