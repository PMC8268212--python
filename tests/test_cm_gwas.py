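"""Greedy LD-independent selection, LD expansion and the conditional loop."""

import numpy as np
import pytest
from scipy import stats

from cmgwas import (build_grm, expand_ld, ld_r2, run_cm_gwas,
                    select_independent)
from cmgwas.meta_stats import MetaResult
from cmgwas.synthetic_data import QTLSpec, SimConfig, simulate_dataset, \
    simulate_genes

from conftest import make_genotypes


def _meta_for(gm, chisq, df=4):
    chisq = np.asarray(chisq, float)
    p = stats.chi2.sf(chisq, df)
    return MetaResult(gm.variant_keys(), gm.chrom_of(), gm.positions(),
                      chisq, p, df, np.zeros(len(chisq), dtype=bool))


def _greedy_oracle(gm, meta, p_threshold, r2_threshold, already=()):
    """Independent brute-force re-implementation of the selection rule using
    per-pair ld_r2 calls."""
    keys = gm.variant_keys()
    chroms = gm.chrom_of()
    out = []
    for chrom in dict.fromkeys(chroms):
        cand = [j for j in range(len(keys))
                if chroms[j] == chrom and meta.p[j] < p_threshold
                and keys[j] not in set(already)]
        cand = [j for j in cand
                if not any(chroms[gm.key_index()[a]] == chrom
                           and np.nan_to_num(ld_r2(gm, keys[j], a)) > r2_threshold
                           for a in already)]
        while cand:
            best = sorted(cand, key=lambda j: (-meta.chisq[j],
                                               meta.pos[j], keys[j]))[0]
            out.append(keys[best])
            cand = [j for j in cand if j != best
                    and not np.nan_to_num(ld_r2(gm, keys[best], keys[j])) > r2_threshold]
    return out


class TestSelectIndependent:
    def test_single_significant_variant(self, rng):
        gm = make_genotypes(rng.integers(0, 3, size=(80, 5)).astype(float))
        chisq = np.array([1.0, 2.0, 60.0, 1.5, 0.5])
        sel = select_independent(_meta_for(gm, chisq), gm)
        assert sel == [gm.variant_keys()[2]]

    def test_strong_ld_pair_keeps_best_only(self, rng):
        base = rng.integers(0, 3, size=80).astype(float)
        gm = make_genotypes(np.column_stack([base, base, rng.integers(0, 3, 80)]))
        chisq = np.array([40.0, 60.0, 1.0])
        sel = select_independent(_meta_for(gm, chisq), gm)
        assert sel == [gm.variant_keys()[1]]

    def test_three_variant_partial_ld(self, rng):
        """r²(1,2) high, r²(1,3) and r²(2,3) low, significance 1 > 2 > 3:
        variants 1 and 3 are selected, 2 is tagged away."""
        v1 = rng.binomial(2, 0.4, 300).astype(float)
        noise = rng.binomial(2, 0.4, 300).astype(float)
        v2 = np.where(rng.random(300) < 0.7, v1, noise)   # correlated with v1
        v3 = rng.binomial(2, 0.4, 300).astype(float)       # independent
        gm = make_genotypes(np.column_stack([v1, v2, v3]))
        k = gm.variant_keys()
        assert ld_r2(gm, k[0], k[1]) > 0.1
        assert ld_r2(gm, k[0], k[2]) < 0.1 and ld_r2(gm, k[1], k[2]) < 0.1
        meta = _meta_for(gm, [70.0, 60.0, 50.0])
        sel = select_independent(meta, gm)
        assert sel == [k[0], k[2]]
        assert sel == _greedy_oracle(gm, meta, 1e-5, 0.1)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 120, 12
        base = rng.binomial(2, 0.35, size=(n, 1)).astype(float)
        cols = [np.where(rng.random(n) < rng.uniform(0.2, 0.95), base[:, 0],
                         rng.binomial(2, 0.35, n)) for _ in range(m)]
        gm = make_genotypes(np.column_stack(cols),
                            chroms=["chr1"] * 6 + ["chr2"] * 6)
        chisq = rng.uniform(0, 80, size=m)
        meta = _meta_for(gm, chisq)
        already = [gm.variant_keys()[1]]
        assert (select_independent(meta, gm, already_selected=already)
                == _greedy_oracle(gm, meta, 1e-5, 0.1, already))

    def test_empty_selection_is_valid(self, rng):
        gm = make_genotypes(rng.integers(0, 3, size=(50, 4)).astype(float))
        assert select_independent(_meta_for(gm, [1.0, 2.0, 3.0, 1.0]), gm) == []

    def test_tie_broken_by_smaller_position(self, rng):
        gm = make_genotypes(rng.integers(0, 3, size=(200, 3)).astype(float))
        sel = select_independent(_meta_for(gm, [55.0, 55.0, 1.0]), gm)
        assert sel[0] == gm.variant_keys()[0]


class TestExpandLD:
    def test_singleton_region(self, rng):
        gm = make_genotypes(rng.integers(0, 3, size=(100, 4)).astype(float))
        meta = _meta_for(gm, [60.0, 1.0, 1.0, 1.0])
        k = gm.variant_keys()
        exp = expand_ld([k[0]], meta, gm)
        assert exp[k[0]] == [(k[0], 1.0)]

    def test_whole_block_expansion(self):
        """In a zero-switch block with every variant significant, the whole
        block lands in one expansion region."""
        cfg = SimConfig(n_animals=120, n_chromosomes=1,
                        variants_per_chromosome=20, block_len_mean=20.0,
                        switch_prob=0.0, maf_min=0.2, seed=13)
        from cmgwas.synthetic_data import simulate_genotypes
        gm = simulate_genotypes(cfg)
        block = [j for j in range(gm.n_variants)
                 if np.array_equal(gm.dosages[:, j], gm.dosages[:, 0])]
        chisq = np.where(np.isin(np.arange(gm.n_variants), block), 60.0, 0.0)
        k = gm.variant_keys()
        exp = expand_ld([k[block[0]]], _meta_for(gm, chisq), gm)
        assert {m for m, _ in exp[k[block[0]]]} == {k[j] for j in block}

    def test_matches_exhaustive_pair_scan(self, rng):
        gm = make_genotypes(rng.integers(0, 3, size=(150, 10)).astype(float))
        chisq = rng.uniform(20, 70, 10)
        meta = _meta_for(gm, chisq)
        k = gm.variant_keys()
        exp = expand_ld([k[3]], meta, gm, r2_expand=0.05)
        brute = [(kk, np.nan_to_num(ld_r2(gm, k[3], kk)))
                 for j, kk in enumerate(k)
                 if meta.p[j] < 1e-5
                 and (kk == k[3] or np.nan_to_num(ld_r2(gm, k[3], kk)) > 0.05)]
        assert [m for m, _ in exp[k[3]]] == [m for m, _ in brute]
        np.testing.assert_allclose([r for _, r in exp[k[3]]],
                                   [r for _, r in brute], atol=1e-12)


class TestConditionalLoop:
    def test_null_simulation_terminates_empty(self):
        cfg = SimConfig(n_animals=400, n_chromosomes=2,
                        variants_per_chromosome=400, n_traits=4,
                        heritability=0.3, strain_var=0.05, seed=202)
        gm, phen, sm, _ = simulate_dataset(cfg)
        res = run_cm_gwas(phen, gm, sm, grm=build_grm(gm))
        assert res.records == []
        assert len(res.audit) == 1 and not res.truncated

    def test_conditioning_reduces_neighbour_chisq(self):
        """After selecting the causal variant, the multi-trait chi² of its
        strong-LD neighbours collapses relative to cycle 1."""
        T = 4
        eff = np.array([0.5, -0.45, 0.5, 0.0])
        cfg = SimConfig(n_animals=1000, n_chromosomes=1,
                        variants_per_chromosome=300, n_traits=T,
                        heritability=0.2, strain_var=0.05,
                        block_len_mean=25.0, switch_prob=0.02,
                        qtls=[QTLSpec(0, 150, 0.3, eff)], seed=303)
        gm, phen, sm, truth = simulate_dataset(cfg)
        res = run_cm_gwas(phen, gm, sm, grm=build_grm(gm))
        assert len(res.records) >= 1
        causal = truth.qtl_keys[0]
        sel = res.records[0].key
        assert np.nan_to_num(ld_r2(gm, sel, causal)) > 0.8
        keys = res.meta_cycle1.variant_keys
        nb = [j for j, k in enumerate(keys)
              if k != sel and np.nan_to_num(ld_r2(gm, sel, k)) > 0.5]
        assert len(nb) >= 3
        before = np.median(res.meta_cycle1.chisq[nb])
        after = np.median(res.meta_final.chisq[nb])
        assert after < before

    def test_two_qtl_one_chromosome(self):
        """Two QTL 50 variants apart at inter-QTL r² < 0.1: both recovered
        by the conditional loop."""
        T = 4
        cfg = SimConfig(n_animals=1000, n_chromosomes=1,
                        variants_per_chromosome=500, n_traits=T,
                        heritability=0.2, strain_var=0.05,
                        block_len_mean=15.0, switch_prob=0.03,
                        qtls=[QTLSpec(0, 200, 0.3,
                                      np.array([0.5, -0.4, 0.45, 0.0])),
                              QTLSpec(0, 250, 0.25,
                                      np.array([0.0, 0.5, -0.45, 0.4]))],
                        seed=404)
        gm, phen, sm, truth = simulate_dataset(cfg)
        assert np.nan_to_num(ld_r2(gm, *truth.qtl_keys)) < 0.1
        res = run_cm_gwas(phen, gm, sm, grm=build_grm(gm))
        for k in truth.qtl_keys:
            best = max((np.nan_to_num(ld_r2(gm, r.key, k))
                        for r in res.records), default=0.0)
            assert best > 0.8
        assert not res.truncated

    def test_gene_annotation_attached(self):
        cfg = SimConfig(n_animals=600, n_chromosomes=1,
                        variants_per_chromosome=300, n_traits=4,
                        heritability=0.2, strain_var=0.05,
                        qtls=[QTLSpec(0, 150, 0.3,
                                      np.array([0.5, -0.5, 0.5, 0.4]))],
                        seed=505)
        gm, phen, sm, truth = simulate_dataset(cfg)
        pos = int(truth.qtl_keys[0].split(":")[1])
        genes = simulate_genes(gm, density=0.0, seed=1,
                               qtl_positions=[("chr1", pos)])
        res = run_cm_gwas(phen, gm, sm, grm=build_grm(gm), genes=genes)
        assert len(res.records) >= 1
        rec = res.records[0]
        assert any(g.distance == 0 for g in rec.genes)
        assert all(g.distance <= 100_000 for g in rec.genes)
        assert rec.profile.n_significant >= 3
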