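# Methods

## Model

Phenotypes are assumed pre-adjusted for fixed effects, one column per
trait, with unbalanced records (animals may miss any subset of traits).
For one trait and one variant *i* the association model is

    y = 1 μ + s_i α_i + Q q + g + e,
    q ~ N(0, I σq²),  g ~ N(0, G σg²),  e ~ N(0, I σe²),

so that var(y) = G σg² + Q Qᵀ σq² + I σe². `G` is the VanRaden method-1
GRM, W Wᵀ/m with W the column-centred, √(2p(1−p))-scaled dosage matrix
over the m variants with MAF strictly above 0.005. The MAF rule and its
strictness are deliberate: monomorphic and ultra-rare variants carry no
usable relationship information and would blow up the 1/√(2pq) scaling.

Variance components are estimated by REML once per trait *without* any
SNP term, and held fixed for the scan and for all conditional re-scans in
later cycles. Holding them fixed across cycles is a deliberate choice:
conditioning on a handful of variants barely moves the genome-wide
variance decomposition, and a fixed covariance makes cycles deterministic
and cheap. Re-estimating per cycle is possible through the API (estimate
again, inject with `MixedModelScanner.set_variance_components`) but is
not the default.

### REML numerics

For each missingness pattern the GRM submatrix is eigendecomposed once,
G = U D Uᵀ. In the rotated basis the covariance is diagonal plus a
rank-s term (s = number of strains):

    Ṽ = (σg² D + σe² I) + σq² Q̃ Q̃ᵀ,   Q̃ = Uᵀ Q,

so solves, determinants and the REML traces cost O(n s²) per iteration
via the Woodbury identity. This is exact algebra, not an approximation;
it makes a 16-trait analysis of thousands of animals a desk-scale
computation. Iterations are average-information steps with step-halving,
an EM fallback when the AI step fails to improve the restricted
likelihood, and projection of the components to a non-negative floor
(10⁻¹⁰ × var(y)). Convergence is a relative log-likelihood change below
10⁻⁶, capped at 200 iterations. A GRM numerically indistinguishable from
the identity makes σg² and σe² non-separable; this is detected from the
eigenvalue spread and reported as a boundary flag rather than an error.

### GLS scan

Each variant is tested by adding its (rotated) dosage column to the fixed
design — intercept plus any conditioning dosages — under the fixed
covariance. The per-variant effect and SE come from the Schur complement
of the normal equations, vectorized over all variants; the rotated
genotype matrix is computed once per missingness pattern and reused
across traits, conditioning sets and cycles. Variants with zero dosage
variance are skipped, as are variants nearly collinear with the
conditioning set (residual normalized SSQ below 10⁻³, i.e. r² > 0.999);
both carry distinct skip codes in the association table. P-values use the
standard normal (Wald) reference: at the sample sizes this tool targets
(thousands of records) the difference from a t reference is far below
everything else in the error budget.

## Multi-trait statistic

Per variant, the signed t-values across traits are combined as
χ² = tᵀ V⁻¹ t with df = number of traits, where V is the trait-by-trait
Pearson correlation of signed t-values over *all* scanned variants — not
only significant ones, so V reflects the null correlation induced by
shared samples and correlated residuals rather than the QTL themselves.
V is computed once from the cycle-1 unconditional scan and reused in all
later cycles; the updated t-values change the statistic, not the
correlation structure. Near-degenerate V (e.g. duplicated traits) is
repaired by an eigenvalue floor (10⁻⁶) followed by re-normalization to
unit diagonal, and flagged.

A variant untested for some trait (MAF filter or skip) contributes 0 for
that trait with V unchanged. This is conservative — it can only shrink
the χ² — and keeps the df interpretation simple. Subsetting V instead
would change df per variant and make P-values incomparable across
variants.

## The conditional loop

Cycle structure, with defaults P < 10⁻⁵, independence r² ≤ 0.1,
expansion r² > 0.8, at most 20 cycles:

1. Unconditional single-trait scans, all traits.
2. V and the multi-trait statistic.
3. Greedy per-chromosome selection: take the most significant eligible
   variant; every significant variant with r² > 0.1 to it — or to any
   variant selected in *any* earlier cycle on that chromosome — is deemed
   to tag the same causal variant and becomes ineligible; repeat until no
   eligible significant variant remains. Ties in significance break by
   smaller position, then allele. Ranking uses the χ² value directly so
   that P-value underflow cannot scramble the order.
4. Conditional re-scans only on chromosomes that have selections, jointly
   fitting that chromosome's selected variants as fixed covariates.
   Conditioning is per-chromosome only; cross-chromosome covariates would
   mostly add noise since unlinked variants are uncorrelated. A guard
   drops the later-selected member of any conditioning pair with
   r² > 0.95 from the joint fit (flagged in the audit log).
5. The multi-trait statistic is recomputed from the updated t-values;
   selected variants keep the t-values they had at selection.
6. Stop when a cycle selects nothing, or truncate with a warning at the
   cycle cap.

Selected variants are never deselected, even if their conditional
significance would later collapse; such events are visible in the audit
log. Screening eligibility against *all* previous selections (not only
the current cycle's) prevents a later cycle from re-tagging an
already-claimed QTL; this is the stricter reading of the selection rule
and is the package default.

After termination, each selected variant's LD region is expanded with
every significant variant (cycle-1 statistic) at r² > 0.8 on its
chromosome, and annotated with all genes within 100 kb of its position,
boundary inclusive (a gene ending exactly 100,000 bp away is reported).
Pleiotropy profiles mask per-trait signed t-values below |t| = 1.96 by
default (2.0 is available — both thresholds are conventional).

## LD and allele frequencies

r² is the squared Pearson correlation of dosage vectors over jointly
non-missing animals (the PLINK `--r2` genotype-count convention on
unphased data), which is also invariant to allele relabelling d → 2 − d.
Pairs where either vector is constant have undefined LD; callers treat
them as r² = 0 (they can tag nothing) with a logged flag. Missing
dosages are mean-imputed for the GRM (they vanish after centring) and
pairwise-deleted for LD; sequence data at this stage is normally imputed,
so both paths are near no-ops in practice.

## Count-based FDR and inflation factor

FDR = P(1 − A/T)/((A/T)(1 − P)) at threshold P with A significant of T
tested. A = 0 leaves the estimate undefined (reported "NA"), values above
1 are reported as "> 100" — both situations occur routinely for
low-powered traits. The genomic inflation factor is median-based with a
1-df χ² reference, λ = median(χ²₁(P)) / 0.45494 (the exact distribution
median from scipy), chosen because the median is robust to the true
signal in the tail.

## Synthetic data generator

The generator is the package's test bed and defines the conditions under
which the pipeline's claims are verified.

* **Genotypes.** Haplotype blocks (block length 1 + Poisson, mean 20
  variants by default) with one allele frequency per block drawn from a
  log-uniform MAF spectrum on [maf_min, 0.5] (shape parameter skews it
  rarer). Within a block, haplotype alleles come from thresholding a
  latent Gaussian AR(1) chain with lag-1 correlation 1 − 2·switch_prob:
  switch 0 gives identical columns (r² = 1), 0.5 gives independence, and
  r² decays geometrically with distance in between. Blocks are mutually
  independent. Dosage = sum of two independent haplotypes. Variants whose
  realized MAF falls below the floor are dropped; QTL-carrying blocks are
  redrawn instead so planted QTL always survive. A block-copying model was
  chosen over a coalescent simulation because the selection logic depends
  on the r² structure, and this model gives direct, parameterized control
  of exactly that at trivial cost. What it does *not* emulate: recombination
  gradients, LD between blocks, selection signatures, or a realistic site
  frequency spectrum at sequence density.
* **Traits.** y = Σ QTL effects × dosage + Q q + g + e per trait. QTL
  effects are per-allele in phenotypic-SD units (a QTL explains
  ≈ 2pq β² of variance). The polygenic term is drawn as W u/√m with W the
  centred-scaled dosage matrix, so its covariance is *exactly* the
  realized GRM — REML recovery tests are internally consistent by
  construction. Strain proportions are Dirichlet(0.5) admixture rows;
  strain effects are i.i.d. with variance σq². Residuals are correlated
  across traits (default: 0.5 between paired yearling/adult-style traits,
  0.2 background). Variance bookkeeping per trait: σg² = h²,
  σq² = strain_var, σe² = 1 − h² − σq², QTL variance on top. Missingness
  is applied completely at random per trait; real missingness is
  structural (age classes), but the estimator conditions on observed
  records either way, so MCAR is the right minimal model here.
* **Genes.** Uniform random intervals at a configurable density, with
  optional anchor genes placed on top of and > 100 kb away from each
  planted QTL so both ends of the annotation window are exercised.

## Test conditions and what they show

* Null calibration uses 16 traits, n = 1000 animals, ≈ 5200 exchangeable
  variants (no LD), unbalanced per-trait records: per-trait λ must fall
  in [0.9, 1.1] and the multi-trait P < 0.01 rate inside the exact
  binomial 99 % interval. Exchangeable variants are used deliberately —
  under LD the binomial and Kolmogorov–Smirnov references are no longer
  exact and the check would measure the LD structure, not the statistic.
* QTL recovery runs 20 replicates of n = 2000 animals, 5 × 1000 variants
  in LD blocks, 8 traits, five pleiotropic QTL (|effects| 0.4–0.55 SD on
  4 traits each, mixed signs, MAF 0.15–0.40). Passing means ≥ 80 % of
  replicates recover every QTL at r² > 0.8 to truth, selected sets are
  always pairwise independent, and the loop always terminates. Problem
  sizes were chosen as the smallest at which the mixed model, LD screen
  and conditional loop all operate in their intended regime.
* These simulations validate the *machinery*, not field performance:
  power and FDR on real sequence data depend on imputation quality, LD
  at sequence density and trait architecture, none of which the
  generator attempts to reproduce.

## Known limitations

* Conditioning is within-chromosome; no leave-one-chromosome-out GRM, so
  a very large QTL leaks a little into the polygenic term (proximal
  contamination) and shrinks its own estimate slightly.
* The Wald/normal reference and fixed variance components understate
  uncertainty marginally at small n; with fewer than ~500 records per
  trait, interpret P-values near the threshold with care.
* The eigen-rotation REML holds one n × n eigendecomposition per distinct
  missingness pattern; thousands of distinct patterns (fully idiosyncratic
  missingness) would be slow — group traits by record pattern where
  possible.
* No X-chromosome dosage handling, no dominance or epistatic terms, no
  credible-set/Bayesian fine-mapping; the selection output is a greedy
  tag set, not a posterior.
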