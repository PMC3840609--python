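# Methods

This note records the models, the synthetic-data assumptions, and the
numerical and design choices behind `growthnet`, at the level of detail
a maintainer or reviewer needs to judge what a passing test suite does
and does not demonstrate.

## The mixed-model GWAS

Each trait is analyzed under the additive animal model

    y = Xβ + Z_k g_k + u + e,   u ~ MVN(0, A σ_u²),   e ~ MVN(0, I σ_e²)

with `A` the pedigree numerator relationship matrix (tabular method,
parents before offspring; unknown parents contribute zero) and `Z_k`
the minor-allele count minus one, so genotypes take values −1, 0, +1.
Residuals are homoscedastic and independent; no dominance, imprinting
or multi-QTL terms are fitted.

**Estimation.** `A` is eigendecomposed once per analyzed animal set.
REML then reduces to a one-dimensional profile over the variance ratio
λ = σ_u²/σ_e²: a 41-point log-grid on [10⁻⁶, 10⁶] (plus λ = 0)
followed by bounded scalar minimization between the best grid
neighbours (`xatol` 1e−8). β̂ comes from GLS at the optimum.

**Per-SNP testing.** The ratio λ is held at the null (no-SNP) REML fit
— the standard "estimate once, test many" approximation — while the
overall scale is re-profiled by maximum likelihood in both nested
models. In whitened coordinates the statistic is therefore
`LRT = n·ln(RSS₀/RSS₁)`, referred to χ²(1). Two properties follow:
when σ_u² = 0 the test is *exactly* the OLS likelihood-ratio test, and
the whole SNP dimension vectorizes through Frisch–Waugh
residualization (one QR per trait). Exact per-SNP re-estimation of λ
is available behind `run_gwas(per_snp_reml=True)`. Missing genotypes
are mean-imputed per SNP for testing only; monomorphic SNPs report
(effect = NaN, LRT = 0, p = 1) rather than raising. No genomic control
or multiple-testing correction is applied at this stage — the AWM
cascade deliberately consumes nominal p ≤ 0.05 evidence.

**Fixed effects.** Weight traits carry one categorical covariate
(birth-year-like, 3 levels); metabolite traits carry two (year +
measurement day), mirroring the asymmetric fixed-effect structure of
the motivating design. Designs are checked for collinearity and the
offending columns are named in the error.

**QC.** Samples are filtered first (call rate > 0.98), then SNPs
(call rate > 0.85 and MAF > 0.01), all strict inequalities.

## The AWM cascade

Additive effects are column-standardized (sample SD, n−1 denominator)
over *all* SNPs in the grid **before** any selection, so standardized
values are comparable across traits and unaffected by later filtering.
Selection then proceeds:

1. `S_key`: SNPs with p ≤ 0.05 (inclusive) for at least one key trait.
2. `A_P`: the mean number of supportive traits hit at p ≤ 0.05 by
   `S_key`, kept unrounded (a `round_ap` flag offers nearest-integer
   rounding). Injected SNPs, if any, are ordinary rows here.
3. `S_supp`: all SNPs whose supportive hit count is ≥ `A_P`
   (comparator configurable to strict >, used optionally by the
   metabolite-only network where the two readings of "at least/more
   than" diverge).
4. Gene proximity: a SNP is kept iff its distance to the nearest gene
   span is ≤ 2 500 bp (0 inside the span; boundary kept; ties broken by
   gene start, then id). Distances are to span boundaries, not TSS;
   strand is ignored.
5. One gene – one SNP: per gene, the SNP with the most traits at
   p ≤ 0.05; ties by lowest mean p over all traits, then lowest
   position, then id.

Externally computed SNPs (the manual-injection path for causal
variants absent from the chip) join the grid *before* standardization
and behave identically afterwards; their gene assignment is pinned.
Rows are sorted by chromosome and position, so the AWM is a pure
function of its inputs.

Note on the spec'd invariant "selection is monotone in the p-value
threshold": that holds for the key stage by construction and is tested
there; it is **not** a theorem for the supportive stage, because
raising the threshold moves `A_P` as well.

## PCIT

For gene pairs the raw statistic is the Pearson correlation of their
standardized-effect profiles across the (≥ 3) trait columns. For every
trio (x, y, z) the three first-order partials

    r_xy·z = (r_xy − r_xz r_yz) / sqrt((1 − r_xz²)(1 − r_yz²))

are computed and the trio's tolerance is the mean partial-to-direct
ratio, ε = mean(r_xy·z/r_xy, r_xz·y/r_xz, r_yz·x/r_yz), excluding
ratios whose direct correlation is below 10⁻¹² in magnitude (if all
three are excluded, or any partial is undefined, the trio is skipped
for that pair). The pair (x, y) is declared non-significant only if
**every** admissible z dominates it, i.e. |r_xy| < |ε·r_xz| and
|r_xy| < |ε·r_yz| for all z; with no trio evidence (n < 3) all nonzero
pairs are kept, with a warning. Consequently a conditioner
uncorrelated with a pair can never eliminate it, and zero correlations
are never significant.

Two implementations exist: a plain-Python triple loop (normative) and
a numba-compiled twin with identical operation order and strict IEEE
semantics, so their outputs are compared for *exact* equality, not
approximate agreement.

Edges of the final network are the PCIT-significant pairs with
|r| ≥ 0.80 (inclusive). The 0.80 filter applies to the pairwise
profile correlation — the quantity PCIT adjudicates — not to any
single trio's partial value; the signed r is stored as edge metadata
and ignored by the topology. "Genes in the network" counts nodes with
degree ≥ 1; isolated AWM genes remain present with degree 0.

## Network analyses

* **Permutation null.** Each replicate independently permutes every
  AWM trait column across genes (preserving all marginals exactly) and
  reruns PCIT + thresholding. Replicate seeds are master seed + index.
* **Metabolite-only network.** Key-trait columns are dropped, the
  supportive-count rule is applied against the *full* analysis' `A_P`,
  and the usual cascade follows; overlap with the full network is the
  intersection of node sets and of unordered edge sets.
* **Ego subnetworks** are full induced subgraphs on a gene plus its
  direct partners (neighbor–neighbor edges included).
* **MCODE** follows the published algorithm at its default settings
  (degree cutoff 2, node-score cutoff 0.2, 2-core requirement, haircut
  on, fluff off, depth 100): vertex weight = highest k-core level of
  the closed neighborhood × that core's density; complexes grow from
  the highest-weight unvisited seed, admitting unvisited neighbours
  within the score cutoff; complexes lacking a 2-core are discarded,
  singly-connected members shaved; clusters are scored density × size.
* **Enrichment** is an exact binomial upper tail
  P(X ≥ n_observed), X ~ Bin(n annotated list genes, term frequency
  among annotated reference genes), one-sided (over-representation
  only), with unannotated genes excluded from both totals and
  Bonferroni over the number of terms tested. Annotation content is
  user-supplied; no ontology graph propagation is performed.

## The synthetic F2 cross

The generator emulates the study conditions the pipeline targets:

* **Pedigree:** two founder pools (default 10 + 10), 40 F1 from
  cross-pool matings, 150 F2 from distinct F1 pairs. Phenotypes are
  generated for the final generation.
* **Genotypes:** 5 chromosomes × 200 SNPs, 100 cM each (Haldane map,
  recombination fraction (1 − e^(−2d/100))/2 per adjacent-SNP gap,
  free recombination across chromosomes). Founder haplotypes are drawn
  at Hardy–Weinberg and linkage equilibrium at one frequency per SNP
  (uniform on [0.1, 0.9]), shared by both pools — so null SNPs carry
  no systematic breed divergence and no genome-wide admixture
  disequilibrium. Genotypes are coded minor-count − 1, with the
  coding-flip record kept so planted effects stay oriented to a
  consistent founder allele.
* **Planted modules:** three modules of 10 genes. Causal SNPs
  segregate divergently between the pools (0.85 vs 0.15), sit in tight
  ~1 cM clusters, and each module owns a disjoint chromosome set so
  that cross-module genotype correlation reflects only the cross
  design, never physical linkage. Every module loads 0.6 trait-SD
  effects on both key weight traits and on a module-specific,
  sign-mixed subset of metabolites; the three patterns are far from
  collinear, which keeps cross-module effect profiles well below the
  0.80 edge threshold. Within-module gene pairs are the ground-truth
  edges.
* **Phenotypes:** 13 traits in four blocks (2 weights, 2 amino acids,
  6 acylcarnitines, 3 phospho-/sphingolipids). y = categorical fixed
  effects + Σ Z·b + u + e with u ~ MVN(0, A σ_u²) given a within-block
  trait correlation of 0.6 (so the trait redundancy structure shows
  the four clusters), e iid. Defaults σ_u² = 0.4, σ_e² = 0.6 — the
  baseline heritability of 0.4 is a configuration choice in the
  0.3–0.5 range typical for growth and metabolite traits, not a claim
  about any particular population.

**What the generator does not emulate:** real bovine LD maps and
marker densities, mass-spectrometry measurement-noise structure,
selection or non-random mating, genotyping error, sex effects. Passing
recovery tests therefore show the pipeline's statistics behave as
designed under a faithful F2 sampling scheme — not that any particular
real dataset would yield a particular network.

## Problem sizes and numerical details

The default desk-scale scenario (150 F2, 1 000 SNPs, 13 traits,
3 × 10-gene modules) runs the full pipeline in well under a minute;
calibration and recovery checks use 100 replicates at n = 300–500 and
a 6 500-test null grid. Degenerate inputs are handled explicitly:
all-SNP-removing QC warns rather than raises; empty AWMs raise with
the failing stage named; n < 3 PCIT inputs and sub-3-gene
metabolite-only AWMs warn and return trivially. Division guards use a
10⁻¹² magnitude floor; REML eigenvalues are clipped at 0 with a −10⁻⁸
PSD tolerance; Cholesky factors add a 10⁻⁸ jitter. All stochastic
stages consume a single master seed, with stage seeds derived
deterministically and kept below 2³¹.

## Known limitations

* The per-trait null-fit approximation understates uncertainty for
  SNPs with very large effects (their variance leaks into σ_u²); the
  `per_snp_reml` flag exists but is quadratic in cost.
* PCIT's "dominated by every conditioner" rule is the permissive
  reading of the trio tolerance; the |r| ≥ 0.80 filter does most of
  the pruning, which matches how the method is used in practice.
* The binomial enrichment test treats genes as exchangeable; no
  correction for gene length, SNP density or annotation bias.
* MCODE's fluff post-processing is not implemented (off by default in
  the published tool as used here); requesting it raises.
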