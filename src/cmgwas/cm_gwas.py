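"""The stepwise conditional multi-trait GWAS loop.

Each cycle: (1) single-trait mixed-model scans (conditional after cycle 1);
(2) multi-trait chi² from the signed t-values; (3) greedy per-chromosome
selection of the most significant variants that are LD-independent
(r² ≤ 0.1) of each other and of everything selected in earlier cycles;
(4) conditional re-scans on chromosomes that have selections, jointly
fitting the selected variants as fixed covariates; (5) the multi-trait
statistic is recomputed from the updated t-values, with selected variants
keeping the t-values they had when selected; (6) repeat until a cycle
selects nothing. Finally each selected variant's LD region is expanded with
all significant variants at r² > 0.8 and annotated with nearby genes.

The trait correlation matrix V is computed once from the cycle-1
unconditional scan and reused; selected variants are never deselected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotate import GeneAnnotation, PleiotropyProfile, nearest_genes, \
    pleiotropy_profile
from .grm_ld import GRM, _pairwise_r2, build_grm
from .io_formats import GeneSet, GenotypeMatrix, PhenotypeTable, StrainMatrix, \
    align_animals
from .meta_stats import MetaResult, TraitCorr, meta_analysis, multitrait_chisq
from .mlm_engine import AssocTable, MixedModelScanner

logger = logging.getLogger("cmgwas")

P_THRESHOLD = 1e-5
R2_INDEPENDENCE = 0.1
R2_EXPAND = 0.8
R2_CONDITION_GUARD = 0.95
MAX_CYCLES = 20
T_REPORT = 1.96


@dataclass
class QTLRecord:
    """A selected independent putative causal variant."""

    key: str
    chrom: str
    pos: int
    cycle: int
    chisq: float
    meta_p: float
    t_profile: np.ndarray
    trait_names: list[str]
    profile: PleiotropyProfile
    ld_members: list[tuple[str, float]] = field(default_factory=list)
    ld_span: int = 0
    genes: list[GeneAnnotation] = field(default_factory=list)


@dataclass
class CMResult:
    records: list[QTLRecord]
    audit: list[dict]
    assoc_cycle1: AssocTable
    trait_corr: TraitCorr
    meta_cycle1: MetaResult
    meta_final: MetaResult
    truncated: bool = False


def _rank_order(chisq: np.ndarray, pos: np.ndarray,
                alts: np.ndarray) -> np.ndarray:
    """Indices sorted by decreasing significance; ties broken by smaller
    position, then lexicographic alternative allele."""
    return np.lexsort((alts, pos, -chisq))


def select_independent(meta: MetaResult, genotypes: GenotypeMatrix,
                       p_threshold: float = P_THRESHOLD,
                       r2_threshold: float = R2_INDEPENDENCE,
                       already_selected: Sequence[str] = ()) -> list[str]:
    """One cycle of greedy per-chromosome selection.

    Significant variants with r² > ``r2_threshold`` to the current pick — or
    to *any* variant selected in an earlier cycle on that chromosome — are
    considered to tag the same causal variant and are ineligible. Returns
    the new selections in selection order (chromosomes in genotype order).
    """
    keys = np.asarray(meta.variant_keys)
    alts = genotypes.variant_meta["alt"].to_numpy(dtype=object).astype(str)
    sig = meta.significant(p_threshold)
    selected_prev = set(already_selected)
    out: list[str] = []
    dosages = genotypes.dosages
    key_idx = genotypes.key_index()
    for chrom in genotypes.variant_meta["chrom"].unique():
        on_chrom = (genotypes.chrom_of() == chrom)
        cand = np.where(on_chrom & sig)[0]
        cand = np.array([i for i in cand if keys[i] not in selected_prev],
                        dtype=int)
        if cand.size == 0:
            continue
        eligible = np.ones(cand.size, dtype=bool)
        # screen against earlier-cycle selections on this chromosome
        for prev in already_selected:
            j = key_idx.get(prev)
            if j is None or genotypes.chrom_of()[j] != chrom:
                continue
            r2, _ = _pairwise_r2(dosages[:, j], dosages[:, cand])
            eligible &= ~(np.nan_to_num(r2) > r2_threshold)
        order = _rank_order(meta.chisq[cand], meta.pos[cand], alts[cand])
        pos_in_order = {c: r for r, c in enumerate(cand[order])}
        while eligible.any():
            live = cand[eligible]
            best = min(live, key=lambda c: pos_in_order[c])
            out.append(str(keys[best]))
            r2, _ = _pairwise_r2(dosages[:, best], dosages[:, cand])
            eligible &= ~(np.nan_to_num(r2) > r2_threshold)
            eligible[cand == best] = False
    return out


def expand_ld(selected: Sequence[str], meta: MetaResult,
              genotypes: GenotypeMatrix, r2_expand: float = R2_EXPAND,
              p_threshold: float = P_THRESHOLD
              ) -> dict[str, list[tuple[str, float]]]:
    """For each selected variant: every significant variant (in the
    unconditional cycle-1 meta-analysis) on the same chromosome with
    r² > ``r2_expand``, the variant itself included."""
    keys = np.asarray(meta.variant_keys)
    sig = meta.significant(p_threshold)
    key_idx = genotypes.key_index()
    chroms = genotypes.chrom_of()
    out: dict[str, list[tuple[str, float]]] = {}
    for k in selected:
        j = key_idx[k]
        cand = np.where(sig & (chroms == chroms[j]))[0]
        r2, _ = _pairwise_r2(genotypes.dosages[:, j],
                             genotypes.dosages[:, cand])
        r2 = np.nan_to_num(r2)
        members = [(str(keys[c]), float(r)) for c, r in zip(cand, r2)
                   if r > r2_expand or c == j]
        out[k] = sorted(members, key=lambda kr: key_idx[kr[0]])
    return out


def _guard_conditioning(keys: list[str], genotypes: GenotypeMatrix,
                        r2_guard: float = R2_CONDITION_GUARD
                        ) -> tuple[list[str], list[str]]:
    """Drop later-selected members whose r² with an earlier member exceeds
    the guard — keeps the joint fit numerically stable."""
    kept: list[str] = []
    dropped: list[str] = []
    idx = genotypes.key_index()
    for k in keys:
        ok = True
        for prev in kept:
            r2, _ = _pairwise_r2(genotypes.dosages[:, idx[prev]],
                                 genotypes.dosages[:, [idx[k]]])
            if np.nan_to_num(r2[0]) > r2_guard:
                ok = False
                break
        (kept if ok else dropped).append(k)
    if dropped:
        logger.warning("conditioning guard dropped %d near-collinear "
                       "variants: %s", len(dropped), dropped)
    return kept, dropped


def run_cm_gwas(phenos: PhenotypeTable, genotypes: GenotypeMatrix,
                strains: StrainMatrix, grm: GRM | None = None,
                genes: GeneSet | None = None,
                p_threshold: float = P_THRESHOLD,
                r2_independence: float = R2_INDEPENDENCE,
                r2_expand: float = R2_EXPAND,
                maf_threshold: float = 0.005,
                max_cycles: int = MAX_CYCLES,
                t_report: float = T_REPORT,
                gene_window: int = 100_000) -> CMResult:
    """Run the full conditional multi-trait GWAS and return the selected
    independent putative causal variants with LD regions, pleiotropy
    profiles and nearest-gene annotation, plus a per-cycle audit log."""
    genotypes, phenos, strains = align_animals(genotypes, phenos, strains)
    if grm is None:
        grm = build_grm(genotypes, maf_threshold)
    scanner = MixedModelScanner(phenos, genotypes, strains, grm, maf_threshold)

    assoc1 = _scan_unconditional(scanner, phenos, genotypes)
    meta1, corr = meta_analysis(assoc1)

    key_idx = genotypes.key_index()
    keys_arr = np.asarray(meta1.variant_keys)
    t_current = assoc1.t.copy()
    meta = meta1
    selected: dict[str, dict] = {}       # key → selection facts
    sel_by_chrom: dict[str, list[str]] = {}
    audit: list[dict] = []
    truncated = False

    cycle = 0
    while True:
        cycle += 1
        new = select_independent(meta, genotypes, p_threshold,
                                 r2_independence, list(selected))
        n_sig = int(np.sum(meta.significant(p_threshold)
                           & ~np.isin(keys_arr, list(selected))))
        audit.append({"cycle": cycle, "n_significant": n_sig,
                      "n_selected": len(new), "selected": list(new)})
        logger.info("cycle %d: %d significant, %d newly selected",
                    cycle, n_sig, len(new))
        if not new:
            break
        for k in new:
            j = key_idx[k]
            selected[k] = {"cycle": cycle, "chisq": float(meta.chisq[j]),
                           "p": float(meta.p[j]),
                           "t": t_current[j].copy()}
            sel_by_chrom.setdefault(genotypes.chrom_of()[j], []).append(k)
        if cycle >= max_cycles:
            truncated = True
            audit.append({"cycle": cycle, "warning":
                          f"max_cycles={max_cycles} reached with selections "
                          "still occurring; loop truncated"})
            logger.warning("CM-GWAS truncated at max_cycles=%d", max_cycles)
            break

        # conditional re-scan restricted to chromosomes with selections
        for chrom, chrom_keys in sel_by_chrom.items():
            fit_keys, dropped = _guard_conditioning(chrom_keys, genotypes)
            if dropped:
                audit[-1].setdefault("conditioning_guard_dropped", []).extend(dropped)
            cols = np.where(genotypes.chrom_of() == chrom)[0]
            for t in range(phenos.n_traits):
                ccols, alpha, se, skip = scanner.scan_trait(t, cols, fit_keys)
                with np.errstate(invalid="ignore", divide="ignore"):
                    t_current[ccols, t] = alpha / se
        # selected variants keep the t-values they had when selected
        for k, facts in selected.items():
            t_current[key_idx[k]] = facts["t"]
        chisq, p = multitrait_chisq(t_current, corr)
        undefined = np.isnan(t_current).all(axis=1)
        meta = MetaResult(list(keys_arr), meta1.chrom, meta1.pos, chisq, p,
                          corr.n_traits, undefined)

    # post-hoc independence check (belt and braces, logged not raised)
    _assert_independence(selected, sel_by_chrom, genotypes, r2_independence)

    expansions = expand_ld(list(selected), meta1, genotypes, r2_expand,
                           p_threshold)
    positions = genotypes.positions()
    records: list[QTLRecord] = []
    for k, facts in selected.items():
        j = key_idx[k]
        members = expansions.get(k, [(k, 1.0)])
        mem_pos = [positions[key_idx[mk]] for mk, _ in members]
        span = int(max(mem_pos) - min(mem_pos)) if mem_pos else 0
        gene_hits = (nearest_genes(genotypes.chrom_of()[j], int(positions[j]),
                                   genes, gene_window)
                     if genes is not None else [])
        prof = pleiotropy_profile(facts["t"], phenos.trait_names, t_report)
        records.append(QTLRecord(
            key=k, chrom=str(genotypes.chrom_of()[j]), pos=int(positions[j]),
            cycle=facts["cycle"], chisq=facts["chisq"], meta_p=facts["p"],
            t_profile=facts["t"], trait_names=list(phenos.trait_names),
            profile=prof, ld_members=members, ld_span=span, genes=gene_hits))
    records.sort(key=lambda r: (list(genotypes.variant_meta["chrom"].unique())
                                .index(r.chrom), r.pos))
    return CMResult(records, audit, assoc1, corr, meta1, meta,
                    truncated=truncated)


def _scan_unconditional(scanner: MixedModelScanner, phenos: PhenotypeTable,
                        genotypes: GenotypeMatrix) -> AssocTable:
    from .mlm_engine import scan_all_traits

    return scan_all_traits(phenos, genotypes, scanner.strains,
                           scanner.grm, scanner.maf_threshold,
                           scanner=scanner)


def _assert_independence(selected: dict, sel_by_chrom: dict,
                         genotypes: GenotypeMatrix, r2_threshold: float) -> None:
    idx = genotypes.key_index()
    for chrom, keys in sel_by_chrom.items():
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                r2, _ = _pairwise_r2(genotypes.dosages[:, idx[a]],
                                     genotypes.dosages[:, [idx[b]]])
                if np.nan_to_num(r2[0]) > r2_threshold:
                    logger.warning(
                        "selected pair (%s, %s) on %s has r²=%.3f above the "
                        "independence threshold — conditional significance "
                        "drop is never grounds for deselection", a, b, chrom,
                        r2[0])


def pairwise_selected_r2(result: CMResult,
                         genotypes: GenotypeMatrix) -> list[tuple[str, str, float]]:
    """All within-chromosome pairwise r² among selected variants (for audits
    and the independence invariant)."""
    idx = genotypes.key_index()
    by_chrom: dict[str, list[str]] = {}
    for r in result.records:
        by_chrom.setdefault(r.chrom, []).append(r.key)
    out = []
    for chrom, keys in by_chrom.items():
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                r2, _ = _pairwise_r2(genotypes.dosages[:, idx[a]],
                                     genotypes.dosages[:, [idx[b]]])
                out.append((a, b, float(np.nan_to_num(r2[0]))))
    return out
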