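# Methods

## The analysis

`snp2net` implements an integrative candidate-gene discovery procedure for
complex disease. The inputs are (a) a list of disease-associated SNPs
replicated across GWASs, (b) cis-eQTL associations from a genotyped,
expression-profiled cohort, (c) a collection of tissue-specific
coexpression modules treated as opaque gene sets, (d) a map of
genome-wide-significant eSNP↔gene relationships, (e) a pairwise LD table,
and (f) GWAS summary statistics from an independent case–control study.

The chain is:

1. **cis trait mapping.** Each disease SNP is tested against the expression
   of every gene within a cis window (default 1 Mb, boundary inclusive,
   gene anchored at its start coordinate) using the Kruskal–Wallis rank
   test; genes with p < 0.05 (uncorrected, strict inequality) in any tissue
   become that SNP's *expression traits*. The relaxed threshold is
   deliberate: the downstream genetic validation acts as the filter. When a
   precomputed eQTL association table is supplied its p-values are trusted
   and the test is bypassed. Monomorphic SNPs and SNPs without positions
   are skipped and counted in the run report.
2. **Module selection and scoring.** Modules containing at least one trait
   are the *disease modules*. Every gene in a disease module receives the
   disease score Σᵢ 1/Sᵢ over the disease modules containing it (Sᵢ the
   module size); the background score is the same sum over the whole
   collection. Because each module of size S contributes exactly S·(1/S) = 1,
   the scores conserve mass: Σ_genes disease score = #disease modules and
   Σ_genes background score = #modules. This identity is asserted to 1e-9
   on every run. Genes are ranked 1 = highest within each list (ties broken
   lexicographically by gene symbol, giving strictly sequential,
   reproducible ranks) and Δrank = background rank − disease rank. Genes
   absent from every disease module get no record; each gene's rank is
   computed within its own list.
3. **Enrichment.** Expression traits and genes adjacent to the disease
   SNPs are removed (they would trivially score well). At each
   disease-score percentile cut-off (default 0, 75, 90, 95, 97.5, 99;
   thresholds by linear interpolation, membership at score ≥ threshold) the
   candidate set is split at its own median Δrank — strictly above goes to
   the top half, ties at the median to the bottom half. Each half is mapped
   to its genome-wide-significant eSNPs, the SNP set is expanded one hop
   with LD partners at R² strictly > 0.8 (no transitive closure: the intent
   is to bridge genotyping platforms, not to walk LD blocks), and the
   fraction of SNPs with GWAS p strictly < 0.05 is recorded. The
   percentage is per unique SNP, not per gene; SNPs absent from the GWAS
   table are dropped from numerator and denominator and counted.
4. **Permutation null models.** Model 1 (*half_genes*): within one
   cut-off's candidate set, draw ⌊n/2⌋ genes without replacement, rerun
   map→expand→fraction; 10,000 replicates by convention. This conditions
   on the set and nulls the Δrank split. Model 2 (*random_traits*): redraw
   the initial expression traits uniformly from the module gene universe
   (all genes in ≥ 1 module, the true traits included) and rerun the whole
   analysis; 1,000 replicates by convention. Empirical p-values use the
   add-one estimator (1 + #{null ≥ observed})/(1 + n), ties counted
   against significance, so p ∈ [1/(n+1), 1] and never 0. Replicates with
   no GWAS overlap are excluded from the null and counted. Each replicate
   draws from an independent seeded substream, so results are independent
   of execution order.

## Synthetic data model

The generator produces all six inputs with a plantable signal so every
stage is testable without the access-controlled cohorts such analyses are
usually run on.

* **Genotypes** are Binomial(2, MAF) per SNP, MAF ~ Uniform(maf_range),
  independent across SNPs. Cohorts whose expected minor-homozygote count
  falls below 3 are refused (the Kruskal–Wallis test downstream needs all
  genotype classes populated).
* **Expression** is unit-SD Gaussian noise; each designated (disease SNP,
  cis gene) pair adds `cis_effect_size` per allele copy. Since the
  association test is rank-based, the noise family is immaterial to
  validity; Gaussian is the simplest choice. Positions lie on one synthetic
  chromosome with uniformly spaced gene anchors (default 100 kb) and each
  disease SNP adjacent to its designated cis gene, so 1 Mb window
  semantics are identical to real coordinates.
* **Modules** have sizes uniform over `module_size_range` and membership
  sampled without replacement with per-gene lognormal propensity weights
  (σ = `hub_sigma`), drawn by the Gumbel top-k trick. The hub structure is
  essential, not cosmetic: real coexpression collections contain genes
  present in very many modules, and those genes populate the top of the
  disease-score list with *small* Δrank. Without them, the top score
  quantile would contain only planted genes and the median-Δrank split —
  the statistic the validation rests on — would have nothing to separate.
  Planted true genes are additionally swapped into trait-containing
  modules with probability `cooccurrence_prob`, preserving module size.
* **The eSNP map** gives each gene Poisson(`esnp_rate`) eSNPs; genes
  drawing zero are unmappable, as in real genome-wide-significance maps.
* **LD proxies** arrive as Poisson(`ld_proxy_rate`) partners per eSNP with
  R² ~ Uniform(r2_range); proxies of true-gene eSNPs inherit the signal.
* **GWAS p-values** are Uniform(0,1) except for eSNPs (and proxies) of
  true genes, which draw Beta(a, 1) with a = `signal_beta_a`, giving the
  closed-form tail P(p < α) = α^a used by the analytic tests
  (0.05^0.3 ≈ 0.407). Each SNP is on the GWAS platform with probability
  `gwas_coverage` (default 0.9), exercising the platform-overlap path that
  motivates LD expansion; coverage 1.0 puts every SNP on the platform.

Every generator stage draws from `default_rng([seed, stage_id])`:
identical config + seed reproduces every table bit-for-bit in any call
order.

**Default study conditions.** The defaults mirror the data regime the
method was designed for: 1,008 individuals, 32 disease SNPs, 14,000 genes,
2,326 modules of 10–120 genes, ~25% of modules containing a trait, 30 true
genes, signal shape a = 0.3. `cis_effect_size` = 0.3 corresponds to a cis
eQTL explaining ~3–4% of expression variance at intermediate MAF — a
moderate, realistic effect that the 1,008-individual cohort detects
reliably. `cooccurrence_prob` = 0.05 places the true genes' disease scores
in the top percentile alongside comparable hub genes, the regime in which
the Δrank split is informative; the balance point is governed by
S̄·w_top/(n_genes·boost), with hubs dominating below it and planted genes
monopolising the top quantile above it.

**What the generator does not emulate:** realistic LD block structure
(proxies are star-shaped around each eSNP), population stratification,
between-gene expression correlation beyond module co-membership, and any
symbol-level gene identity. Passing tests therefore demonstrate
correctness and calibration of the *procedure*, not performance on real
cohorts, where confounding and correlated markers can inflate both
enrichment and its nulls.

## Test-suite problem sizes

The suite fixes a scaled-down analogue of the study conditions for its
replicated checks: 6,000 genes, 600 modules of 30–100 genes, 25 disease
SNPs, 30 true genes, hub σ = 1.2, elevation 0.15, Beta shape 0.3 (signal)
or cis effect 0 / shape 1 / elevation 0 (null). These sizes keep the top
percentile sets large enough (~50 genes, ~10² SNPs after expansion) for
fractions to be statistically stable while whole-pipeline replicates stay
cheap; calibration runs use 100 independent null datasets with 100
random-trait replicates each, and the power check 50 seeds. The
acceptance script runs the full default scale with 10,000 half-gene and
1,000 random-trait replicates.

## Numerical and design choices

* Kruskal–Wallis uses the tie-corrected H with a χ²(k−1) tail; genotype
  classes with zero members are dropped and df reduced. All-constant
  expression returns H = 0, p = 1 by convention (the tie correction
  degenerates). The χ² tail is an approximation: at n ≤ 5 per group it can
  differ from the exact permutation null by ~0.1, which is inherent to the
  test, not to this implementation; the suite checks the statistic against
  the exact enumerated null directly.
* All boundary conventions are strict-vs-inclusive as follows: cis window
  inclusive (≤ 1 Mb), association and GWAS significance strict (< 0.05),
  LD strict (> 0.8), quantile membership inclusive (≥ threshold), median
  split strict above.
* Duplicate modules (identical gene sets from different sources) are
  retained as distinct score terms.
* The random-traits sampling universe includes the true traits; an
  exclusion flag is available but changes nothing detectable at the
  replicate counts used.
* Scores are kept at full float precision; ranks are the canonical
  comparison quantity. Summation error on the conservation identity is
  ~1e-11 at the default scale, well inside the asserted 1e-9.

## Known limitations

* Single-tissue synthetic expression: the multi-tissue union rule ("trait
  in any tissue") is exercised through the precomputed-table path only.
* The per-gene aggregation variant of the enrichment fraction (gene
  significant if any eSNP is) is not implemented; the per-SNP form is the
  primary and only statistic.
* Gene identifiers are opaque strings; no aliasing or ID mapping.
* Model-1 permutation at low cut-offs resamples thousands of genes per
  replicate and is the slowest stage at full scale; the orchestrator runs
  it at every cut-off, so reduce `perm_half_reps` when low cut-offs are
  included.
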