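"""REML variance components and the GLS association scan."""

import numpy as np
import pytest
from scipy import stats

from cmgwas import (GRM, ValidationError, build_grm, estimate_vc, gwas_scan,
                    scan_all_traits)
from cmgwas.mlm_engine import (SKIP_COLLINEAR, SKIP_CONDITIONING,
                               SKIP_ZERO_VAR, MixedModelScanner,
                               VarianceComponents)
from cmgwas.synthetic_data import QTLSpec, SimConfig, simulate_dataset

from conftest import make_genotypes, make_strains


def _fixed_vc(sg2, sq2, se2, n):
    return VarianceComponents(sg2, sq2, se2, 0.0, n, True, 0)


class TestREML:
    def test_recovers_planted_components(self):
        """Across seeded replicates the REML means land within 3 replicate
        SEs of the generative (sigma_g², sigma_q², sigma_e²)."""
        truth = np.array([0.4, 0.05, 0.55])
        ests = []
        for rep in range(8):
            cfg = SimConfig(n_animals=800, n_chromosomes=2,
                            variants_per_chromosome=1000, n_traits=1,
                            heritability=truth[0], strain_var=truth[1],
                            seed=200 + rep)
            gm, phen, sm, _ = simulate_dataset(cfg)
            vc = estimate_vc(phen.values[:, 0], sm, build_grm(gm))
            assert vc.converged
            ests.append(vc.as_array())
        ests = np.asarray(ests)
        se = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
        assert np.all(np.abs(ests.mean(axis=0) - truth) <= 3 * se + 1e-6)

    def test_pure_noise_boundary(self):
        """With no structure at all, genomic and strain components collapse
        to (near) zero."""
        cfg = SimConfig(n_animals=500, n_chromosomes=1,
                        variants_per_chromosome=800, n_traits=1,
                        heritability=0.0, strain_var=0.0, seed=33)
        gm, phen, sm, _ = simulate_dataset(cfg)
        vc = estimate_vc(phen.values[:, 0], sm, build_grm(gm))
        assert vc.sigma_g2 < 0.08 and vc.sigma_q2 < 0.08
        assert vc.sigma_e2 == pytest.approx(1.0, abs=0.15)

    def test_identity_grm_flagged(self):
        """G = I makes sigma_g² and sigma_e² non-separable → boundary flag."""
        n = 100
        rng = np.random.default_rng(1)
        grm = GRM(np.eye(n), [f"an{i:04d}" for i in range(n)], [], 0.005)
        sm = make_strains(n, seed=1)
        vc = estimate_vc(rng.standard_normal(n), sm, grm)
        assert any("not separable" in b for b in vc.boundary)

    def test_too_few_records(self):
        grm = GRM(np.eye(40), [f"an{i:04d}" for i in range(40)], [], 0.005)
        y = np.full(40, np.nan)
        y[:10] = 1.0
        with pytest.raises(ValidationError, match="30"):
            estimate_vc(y, make_strains(40), grm)


@pytest.fixture(scope="module")
def null_structure_free():
    cfg = SimConfig(n_animals=400, n_chromosomes=2,
                    variants_per_chromosome=300, n_traits=1,
                    heritability=0.0, strain_var=0.0, block_len_mean=1.0,
                    seed=55)
    return simulate_dataset(cfg)


class TestGLSScan:
    def test_zero_vc_equals_ols(self, null_structure_free):
        """With sigma_g² = sigma_q² = 0 the GLS scan reproduces OLS of y on
        (1, dosage) — effects exactly, SEs via the known-variance formula."""
        gm, phen, sm, _ = null_structure_free
        y = phen.values[:, 0]
        vc = _fixed_vc(0.0, 0.0, float(np.var(y)), len(y))
        assoc = gwas_scan(y, sm, build_grm(gm), gm, vc=vc)
        ones = np.ones(len(y))
        for j in range(0, gm.n_variants, 7):
            if np.isnan(assoc.effects[j, 0]):
                continue
            X = np.column_stack([ones, gm.dosages[:, j]])
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            se = np.sqrt(vc.sigma_e2 * np.linalg.inv(X.T @ X)[1, 1])
            assert assoc.effects[j, 0] == pytest.approx(beta[1], rel=1e-8)
            assert assoc.se[j, 0] == pytest.approx(se, rel=1e-8)

    def test_t_invariant_to_phenotype_rescaling(self, null_structure_free):
        gm, phen, sm, _ = null_structure_free
        grm = build_grm(gm)
        y = phen.values[:, 0]
        a1 = gwas_scan(y, sm, grm, gm, vc=estimate_vc(y, sm, grm))
        y2 = 3.7 * y
        a2 = gwas_scan(y2, sm, grm, gm, vc=estimate_vc(y2, sm, grm))
        ok = ~np.isnan(a1.t[:, 0])
        np.testing.assert_allclose(a1.t[ok, 0], a2.t[ok, 0], rtol=1e-6)

    def test_planted_effect_recovered(self):
        """Mean effect estimate over replicates sits within 3 replicate SEs
        of the planted 0.5 SD allele-substitution effect."""
        est = []
        for rep in range(6):
            cfg = SimConfig(n_animals=800, n_chromosomes=1,
                            variants_per_chromosome=400, n_traits=1,
                            heritability=0.3, strain_var=0.05,
                            qtls=[QTLSpec(0, 200, 0.3, np.array([0.5]))],
                            seed=700 + rep)
            gm, phen, sm, truth = simulate_dataset(cfg)
            grm = build_grm(gm)
            y = phen.values[:, 0]
            assoc = gwas_scan(y, sm, grm, gm)
            j = assoc.variant_keys.index(truth.qtl_keys[0])
            est.append(assoc.effects[j, 0])
        est = np.asarray(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 0.5) <= 3 * se + 1e-3

    def test_null_pvalues_uniform(self, null_structure_free):
        """Null phenotype, no structure: single-trait P-values are uniform
        (KS at alpha = 0.01)."""
        gm, phen, sm, _ = null_structure_free
        y = phen.values[:, 0]
        grm = build_grm(gm)
        assoc = gwas_scan(y, sm, grm, gm)
        p = assoc.p[~np.isnan(assoc.p[:, 0]), 0]
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_conditioning_on_causal_kills_neighbours(self):
        """Conditioning on the causal variant drops the median chi² of its
        LD-block neighbours below the unconditional median."""
        cfg = SimConfig(n_animals=1000, n_chromosomes=1,
                        variants_per_chromosome=300, n_traits=1,
                        heritability=0.2, strain_var=0.05,
                        block_len_mean=25.0, switch_prob=0.02,
                        qtls=[QTLSpec(0, 150, 0.3, np.array([0.5]))],
                        seed=91)
        gm, phen, sm, truth = simulate_dataset(cfg)
        grm = build_grm(gm)
        y = phen.values[:, 0]
        vc = estimate_vc(y, sm, grm)
        causal = truth.qtl_keys[0]
        uncond = gwas_scan(y, sm, grm, gm, vc=vc)
        cond = gwas_scan(y, sm, grm, gm, vc=vc, conditioning=[causal])
        from cmgwas import ld_scan
        keys = gm.variant_keys()
        others = [k for k in keys if k != causal]
        r2 = ld_scan(gm, causal, others).as_dict()
        nb = [uncond.variant_keys.index(k) for k, v in r2.items() if v > 0.5]
        assert len(nb) >= 3
        chi_u = np.median(uncond.t[nb, 0] ** 2)
        chi_c = np.median(np.nan_to_num(cond.t[nb, 0]) ** 2)
        assert chi_c < chi_u

    def test_uncorrelated_conditioning_is_stable(self, null_structure_free):
        """Conditioning on a variant uncorrelated with the tested ones
        barely moves the statistics."""
        gm, phen, sm, _ = null_structure_free
        grm = build_grm(gm)
        y = phen.values[:, 0]
        vc = estimate_vc(y, sm, grm)
        keys = gm.variant_keys()
        other_chrom = [k for k in keys if k.startswith("chr2")][0]
        a1 = gwas_scan(y, sm, grm, gm, vc=vc)
        a2 = gwas_scan(y, sm, grm, gm, vc=vc, conditioning=[other_chrom])
        sel = [j for j, k in enumerate(keys)
               if k.startswith("chr1") and not np.isnan(a1.t[j, 0])]
        diff = a2.t[sel, 0] - a1.t[sel, 0]
        assert np.median(np.abs(diff)) < 0.1
        assert np.corrcoef(a1.t[sel, 0], a2.t[sel, 0])[0, 1] > 0.999

    def test_skip_flags(self):
        rng = np.random.default_rng(5)
        dos = rng.integers(0, 3, size=(120, 4)).astype(float)
        dos[:, 1] = 1.0                      # zero variance, MAF 0.5
        dos[:, 3] = dos[:, 2]                # duplicate → collinear when conditioned
        gm = make_genotypes(dos)
        sm = make_strains(120, seed=2)
        y = rng.standard_normal(120)
        grm = build_grm(gm, maf_threshold=0.0)
        keys = gm.variant_keys()
        assoc = gwas_scan(y, sm, grm, gm, conditioning=[keys[2]],
                          maf_threshold=0.0)
        assert assoc.skip[1, 0] == SKIP_ZERO_VAR
        assert assoc.skip[3, 0] == SKIP_COLLINEAR
        assert assoc.skip[2, 0] == SKIP_CONDITIONING
        assert np.isnan(assoc.t[2, 0])


class TestScanAllTraits:
    def test_identical_traits_identical_results(self):
        cfg = SimConfig(n_animals=300, n_chromosomes=1,
                        variants_per_chromosome=200, n_traits=1,
                        heritability=0.3, seed=44)
        gm, phen, sm, _ = simulate_dataset(cfg)
        from cmgwas import PhenotypeTable
        dup = PhenotypeTable(np.column_stack([phen.values[:, 0]] * 2),
                             ["a", "b"], phen.animal_ids)
        assoc = scan_all_traits(dup, gm, sm, build_grm(gm))
        np.testing.assert_array_equal(assoc.t[:, 0], assoc.t[:, 1])

    def test_all_missing_trait_named_in_error(self):
        cfg = SimConfig(n_animals=100, n_chromosomes=1,
                        variants_per_chromosome=100, n_traits=2, seed=3)
        gm, phen, sm, _ = simulate_dataset(cfg)
        phen.values[:, 1] = np.nan
        with pytest.raises(ValidationError, match="trait02"):
            scan_all_traits(phen, gm, sm, build_grm(gm))

    def test_rescan_bit_identical(self):
        """Re-scanning the same chromosome through the cached scanner gives
        bit-identical results (the conditional loop relies on this)."""
        cfg = SimConfig(n_animals=200, n_chromosomes=2,
                        variants_per_chromosome=150, n_traits=2,
                        heritability=0.3, seed=66)
        gm, phen, sm, _ = simulate_dataset(cfg)
        scanner = MixedModelScanner(phen, gm, sm, build_grm(gm))
        cols = np.where(scanner.chroms == "chr1")[0]
        r1 = scanner.scan_trait(0, cols)
        r2 = scanner.scan_trait(0, cols)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a, b)
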