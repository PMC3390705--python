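# snp2net

Candidate-gene discovery for complex disease by integrating replicated
GWAS SNPs, cis-eQTLs and coexpression modules — with genetic validation of
the candidates by LD-expanded eSNP enrichment against independent GWAS
summary statistics.

## The problem and the method

GWASs yield loci, not mechanisms: most disease-associated SNPs sit in
introns or intergenic regions, and the gene they act through is rarely
obvious. `snp2net` implements a network-based prioritisation chain for
this situation, aimed at statistical geneticists and systems biologists
with access to (or a need to simulate) eQTL cohorts, coexpression module
collections and GWAS summary statistics:

1. Map each replicated disease SNP to its **expression traits**: genes
   within 1 Mb whose expression associates with the SNP genotype
   (Kruskal–Wallis test, uncorrected p < 0.05).
2. Select the coexpression modules containing ≥ 1 trait and score every
   gene by the **inverse-sum coexpression score**

   score(g) = Σᵢ 1/Sᵢ,

   summed over the selected modules containing g, where Sᵢ is the module
   size — co-occurrence with the traits, weighted against membership of
   large modules being cheap. A background score over *all* modules, and
   **Δrank = background rank − disease rank**, separate disease-specific
   prominence from generic hubness.
3. Validate genetically: after excluding the traits themselves and genes
   adjacent to the disease SNPs, take the genes above each disease-score
   quantile (0, 75, 90, 95, 97.5, 99), split each set at its median Δrank,
   map each half back to genome-wide-significant eSNPs, expand with LD
   proxies (R² > 0.8) to bridge genotyping platforms, and record the
   fraction of SNPs with GWAS p < 0.05.
4. Judge that fraction against two permutation nulls: random half-gene
   resampling within each set (10,000×) and full reruns from randomly
   redrawn expression traits (1,000×), with add-one empirical p-values.

A seeded synthetic-data module generates all six inputs — genotypes,
expression, modules with hub structure, eSNP map, LD table, GWAS summary
statistics — with a plantable set of true disease genes, so the whole
chain is testable end to end. See `docs/methods.md` for the model and its
assumptions.

## Worked example

```python
from snp2net import (SimulationConfig, simulate_all, map_cis_traits,
                     select_disease_modules, score_and_rank)

ds = simulate_all(SimulationConfig(seed=1))          # study-scale synthetic data
m = map_cis_traits(ds.disease_snps,
                   genotypes=ds.cohort.genotypes,
                   expression=ds.cohort.expression,
                   snp_positions=ds.cohort.snp_positions,
                   gene_positions=ds.cohort.gene_positions)
dm, present = select_disease_modules(ds.modules, m.trait_genes)
scores = score_and_rank(ds.modules, dm)
print(len(m.trait_genes), len(dm), len(scores))
print(scores.head(3).to_string(index=False))
```

prints

```
66 626 11071
  gene  disease_score  background_score  disease_rank  background_rank  delta_rank
G13012       1.546182          1.546182             1               46          45
G06155       1.171536          1.171536             2               99          97
G07009       0.874865          3.502877             3                1          -2
```

i.e. the 32 disease SNPs map to 66 expression traits, 626 of the 2,326
modules contain at least one trait, and 11,071 genes receive a score. The
two top-ranked genes co-occur specifically with the traits (their whole
background score comes from disease modules, so Δrank is large and
positive); the third is a coexpression hub, prominent everywhere
(background rank 1, Δrank −2). The median-Δrank split in steps 3–4
separates exactly these two kinds, and in this run finds 14.6% of
top-half eSNPs at the 99th percentile with GWAS p < 0.05 vs 6.3% in the
bottom half (empirical p = 0.02 and 0.001 under the two null models).

The same chain is scriptable from the shell:

```bash
snp2net simulate --out-dir data --seed 1
snp2net map-traits --snps data/disease_snps.tsv --eqtl eqtl.tsv --out traits.tsv
snp2net run-all --config pipeline.yaml
```

The packaged table of 32 replicated type 2 diabetes SNPs (the motivating
use case) is available via `snp2net.io.load_packaged_disease_snps()`.

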