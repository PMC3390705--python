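"""Synthetic inputs for the SNP -> eQTL -> coexpression -> GWAS pipeline.

Every external input the pipeline consumes can be generated here with the
statistical structure the analysis assumes, plus a *plantable* signal: a set
of designated true disease genes whose module co-occurrence with the disease
expression traits is elevated and whose eSNPs carry inflated GWAS
association.  With the signal parameters nulled (``cis_effect_size=0``,
``signal_beta_a=1``, ``cooccurrence_prob=0``) every downstream significance
measure is calibrated at its nominal level, which is what the test suite
checks.

Model summary
-------------
* Genotypes: per-SNP ``Binomial(2, MAF)``, MAF uniform in ``maf_range``,
  independent across SNPs (designated LD proxies are separate bookkeeping).
* Expression: unit-variance Gaussian noise; each designated
  (disease SNP, cis gene) pair adds ``cis_effect_size`` per allele copy.
* Positions: one synthetic chromosome, genes uniformly spaced, each disease
  SNP placed adjacent to its designated cis gene (within the 1 Mb window).
* Modules: sizes uniform over ``module_size_range``; membership sampled
  without replacement with gene-level lognormal propensity weights
  (coexpression hubs), via Gumbel top-k; true genes are additionally swapped
  into trait-containing modules with probability ``cooccurrence_prob``.
* GWAS p-values: eSNPs (and LD proxies) of true genes draw
  ``Beta(signal_beta_a, 1)``; everything else ``Uniform(0, 1)``; each SNP is
  present on the GWAS platform with probability ``gwas_coverage``.

All generators are deterministic functions of ``SimulationConfig`` — each
stage draws from ``default_rng([seed, stage_id])``, so identical config and
seed reproduce every table bit-for-bit regardless of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .module_scoring import CoexpressionModule

__all__ = [
    "SimulationConfig",
    "Cohort",
    "SyntheticDataset",
    "designate_planted_genes",
    "generate_cohort",
    "generate_modules",
    "generate_esnp_map",
    "generate_ld_map",
    "generate_gwas_summary",
    "simulate_all",
]

# independent substream per generator stage
_STAGES = {
    "designate": 1,
    "cohort": 2,
    "modules": 3,
    "esnp": 4,
    "ld": 5,
    "gwas": 6,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the real data regimes the pipeline was designed for:
    a 1,008-individual eQTL cohort across three metabolic tissues, 2,326
    tissue-specific coexpression modules over ~14,000 genes, 32 replicated
    disease SNPs, and GWAS summary statistics on a partially overlapping
    SNP platform bridged by LD proxies at R^2 > 0.8.
    """

    n_individuals: int = 1008
    n_snps: int = 200
    n_genes: int = 14000
    n_modules: int = 2326
    module_size_range: tuple = (10, 120)
    n_disease_snps: int = 32
    n_true_genes: int = 30
    cis_effect_size: float = 0.3  # expression shift per allele copy, noise SD = 1
    maf_range: tuple = (0.1, 0.5)
    signal_beta_a: float = 0.3  # Beta(a,1) shape for true-gene eSNP GWAS p-values
    ld_proxy_rate: float = 1.0  # expected proxies per eSNP (Poisson)
    r2_range: tuple = (0.5, 1.0)
    seed: int = 0
    # elevation of true-gene membership in trait-containing modules
    cooccurrence_prob: float = 0.05
    esnp_rate: float = 2.0  # mean genome-wide-significant eSNPs per gene (Poisson)
    gwas_coverage: float = 0.9  # P(SNP present on the GWAS platform)
    hub_sigma: float = 1.0  # lognormal sigma of gene module-membership propensity
    gene_spacing: int = 100_000  # bp between adjacent gene anchors

    def __post_init__(self):
        for name in ("n_individuals", "n_snps", "n_genes", "n_modules",
                     "n_disease_snps", "n_true_genes", "gene_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_true_genes > self.n_genes:
            raise ValueError("n_true_genes exceeds n_genes")
        if self.n_disease_snps > self.n_snps:
            raise ValueError("n_disease_snps exceeds n_snps")
        if self.n_disease_snps + self.n_true_genes > self.n_genes:
            raise ValueError("not enough genes for disjoint traits and true genes")
        if not (0 < self.signal_beta_a <= 1):
            raise ValueError("signal_beta_a must be in (0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range bounds must satisfy 0 < lo <= hi <= 0.5")
        lo, hi = self.r2_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("r2_range bounds must lie in [0, 1]")
        if not (0 <= self.cooccurrence_prob <= 1):
            raise ValueError("cooccurrence_prob must be in [0, 1]")
        if not (0 <= self.gwas_coverage <= 1):
            raise ValueError("gwas_coverage must be in [0, 1]")
        if self.ld_proxy_rate < 0 or self.esnp_rate < 0:
            raise ValueError("rates must be nonnegative")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) & 0x7FFFFFFF, _STAGES[stage]])


def _gene_symbol(i: int) -> str:
    return f"G{i:05d}"


def _disease_rsid(j: int) -> str:
    return f"rs1{j:06d}"


@dataclass(frozen=True)
class Planted:
    """Deterministic designation of trait genes and true disease genes."""

    trait_genes: tuple  # designated cis gene per disease SNP, index-aligned
    true_genes: tuple  # genes with planted module/GWAS signal


def designate_planted_genes(config: SimulationConfig) -> Planted:
    """Pick the disease SNPs' cis genes and the true disease genes.

    The two sets are disjoint: true genes are meant to be *novel* candidates
    reachable only through module co-occurrence, never expression traits
    themselves.
    """
    rng = config.rng("designate")
    picks = rng.choice(
        config.n_genes, size=config.n_disease_snps + config.n_true_genes, replace=False
    )
    traits = tuple(_gene_symbol(i) for i in sorted(picks[: config.n_disease_snps]))
    true = tuple(_gene_symbol(i) for i in sorted(picks[config.n_disease_snps:]))
    return Planted(trait_genes=traits, true_genes=true)


@dataclass
class Cohort:
    """Genotype + expression matrices with genomic coordinates."""

    genotypes: pd.DataFrame  # individuals x SNPs, values in {0,1,2}
    expression: pd.DataFrame  # individuals x genes
    snp_positions: pd.Series  # rsid -> bp on the synthetic chromosome
    gene_positions: pd.Series  # gene symbol -> bp anchor
    planted_pairs: pd.DataFrame  # columns rsid, gene (the designated cis pairs)


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate genotypes and expression with planted cis effects.

    For each designated (disease SNP, cis gene) pair the gene's expression is
    ``baseline + cis_effect_size * genotype + N(0, 1)``; every other gene-SNP
    pair carries no planted effect.  Refuses cohorts too small for the
    downstream Kruskal-Wallis test to see all three genotype classes.
    """
    maf_min = config.maf_range[0]
    if config.n_individuals * maf_min**2 < 3:
        raise ValueError(
            "cohort too small: expected count of the rarest genotype class "
            f"({config.n_individuals * maf_min**2:.2f}) is below 3"
        )
    planted = designate_planted_genes(config)
    rng = config.rng("cohort")

    maf = rng.uniform(*config.maf_range, size=config.n_snps)
    geno = rng.binomial(2, maf, size=(config.n_individuals, config.n_snps))
    expr = rng.normal(0.0, 1.0, size=(config.n_individuals, config.n_genes))

    gene_syms = [_gene_symbol(i) for i in range(config.n_genes)]
    gene_pos = np.arange(1, config.n_genes + 1, dtype=np.int64) * config.gene_spacing
    gene_positions = pd.Series(gene_pos, index=gene_syms, name="position")

    # disease SNP j sits 1 bp from its designated cis gene's anchor;
    # remaining SNPs are scattered uniformly along the chromosome
    rsids = [_disease_rsid(j) for j in range(config.n_disease_snps)]
    rsids += [f"rs9{j:06d}" for j in range(config.n_snps - config.n_disease_snps)]
    snp_pos = np.empty(config.n_snps, dtype=np.int64)
    trait_idx = [int(g[1:]) for g in planted.trait_genes]
    snp_pos[: config.n_disease_snps] = gene_pos[trait_idx] + 1
    snp_pos[config.n_disease_snps:] = rng.integers(
        1, gene_pos[-1] + 1, size=config.n_snps - config.n_disease_snps
    )

    for j, g_idx in enumerate(trait_idx):
        expr[:, g_idx] += config.cis_effect_size * geno[:, j]

    individuals = [f"I{i:04d}" for i in range(config.n_individuals)]
    return Cohort(
        genotypes=pd.DataFrame(geno, index=individuals, columns=rsids),
        expression=pd.DataFrame(expr, index=individuals, columns=gene_syms),
        snp_positions=pd.Series(snp_pos, index=rsids, name="position"),
        gene_positions=gene_positions,
        planted_pairs=pd.DataFrame(
            {"rsid": rsids[: config.n_disease_snps], "gene": list(planted.trait_genes)}
        ),
    )


def _weighted_sample_topk(
    rng: np.random.Generator, log_w: np.ndarray, k: int
) -> np.ndarray:
    """Weighted sampling without replacement via the Gumbel top-k trick."""
    keys = log_w + rng.gumbel(size=log_w.shape)
    return np.argpartition(-keys, k - 1)[:k]


def generate_modules(
    config: SimulationConfig, trait_genes: Iterable[str]
) -> list[CoexpressionModule]:
    """Coexpression modules with hub genes and planted co-occurrence.

    Module sizes are uniform over ``module_size_range``.  Membership is
    weighted by a per-gene lognormal propensity so that some genes are hubs
    present in many modules, as in real coexpression networks — without
    hubs, the top of the disease-score list would contain nothing but the
    planted genes and the rank-difference statistic would be untestable.
    In each module containing a trait gene, every true gene is swapped in
    with probability ``cooccurrence_prob`` (replacing a random member that
    is neither trait nor true gene, preserving the drawn size).
    """
    lo, hi = config.module_size_range
    if not (1 <= lo <= hi <= config.n_genes):
        raise ValueError(
            f"module_size_range {config.module_size_range} exceeds gene universe"
        )
    trait_set = set(trait_genes)
    true_set = set(designate_planted_genes(config).true_genes)
    rng = config.rng("modules")
    log_w = rng.normal(0.0, config.hub_sigma, size=config.n_genes)  # log lognormal
    sizes = rng.integers(lo, hi + 1, size=config.n_modules)
    gene_syms = np.asarray([_gene_symbol(i) for i in range(config.n_genes)], dtype=object)

    modules = []
    for m in range(config.n_modules):
        members = set(gene_syms[_weighted_sample_topk(rng, log_w, int(sizes[m]))])
        if config.cooccurrence_prob > 0 and members & trait_set:
            for tg in sorted(true_set - members):
                if rng.random() >= config.cooccurrence_prob:
                    continue
                swappable = sorted(members - trait_set - true_set)
                if not swappable:
                    break
                out = swappable[rng.integers(len(swappable))]
                members.remove(out)
                members.add(tg)
        modules.append(
            CoexpressionModule(
                module_id=f"M{m:04d}", source="synthetic", genes=frozenset(members)
            )
        )
    return modules


def generate_esnp_map(config: SimulationConfig) -> pd.DataFrame:
    """Genome-wide-significant eSNP <-> gene map.

    Each gene carries ``Poisson(esnp_rate)`` eSNPs; genes drawing zero are
    absent from the map (not every gene has a mappable eQTL).  Returns a
    DataFrame with columns ``gene`` and ``rsid``.
    """
    rng = config.rng("esnp")
    counts = rng.poisson(config.esnp_rate, size=config.n_genes)
    genes, rsids = [], []
    serial = 0
    for i, k in enumerate(counts):
        for _ in range(int(k)):
            genes.append(_gene_symbol(i))
            rsids.append(f"rs2{serial:07d}")
            serial += 1
    return pd.DataFrame({"gene": genes, "rsid": rsids})


def generate_ld_map(
    esnp_map: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, dict]:
    """LD proxy table for the eSNPs.

    Each eSNP acquires ``Poisson(ld_proxy_rate)`` proxy SNPs with R^2 drawn
    uniformly from ``r2_range``; each pair is stored once.  Also returns a
    ``proxy -> source eSNP`` map so that proxies of true-gene eSNPs can
    inherit the planted GWAS signal.
    """
    rng = config.rng("ld")
    esnps = sorted(esnp_map["rsid"].unique())
    rows = []
    proxy_of: dict[str, str] = {}
    serial = 0
    for snp in esnps:
        for _ in range(int(rng.poisson(config.ld_proxy_rate))):
            proxy = f"rs3{serial:07d}"
            serial += 1
            rows.append((snp, proxy, float(rng.uniform(*config.r2_range))))
            proxy_of[proxy] = snp
    table = pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2"])
    return table, proxy_of


def generate_gwas_summary(
    esnp_map: pd.DataFrame,
    true_genes: Iterable[str],
    config: SimulationConfig,
    proxy_of: dict | None = None,
) -> pd.DataFrame:
    """Per-SNP GWAS association p-values with a planted enrichment signal.

    eSNPs of true genes — and, when ``proxy_of`` is given, their LD proxies —
    draw ``p ~ Beta(signal_beta_a, 1)``, so ``P(p < a) = a^shape``; all other
    SNPs draw ``p ~ Uniform(0, 1)``.  Each SNP appears on the platform with
    probability ``gwas_coverage``.  Returns columns ``rsid`` and ``p``.
    """
    rng = config.rng("gwas")
    true_set = set(true_genes)
    signal_esnps = set(esnp_map.loc[esnp_map["gene"].isin(true_set), "rsid"])
    snps = list(dict.fromkeys(esnp_map["rsid"]))
    if proxy_of:
        snps += sorted(proxy_of)
    rows = []
    for snp in snps:
        covered = rng.random() < config.gwas_coverage
        source = proxy_of.get(snp, snp) if proxy_of else snp
        if source in signal_esnps:
            p = float(rng.beta(config.signal_beta_a, 1.0))
        else:
            p = float(rng.uniform())
        if covered:
            rows.append((snp, max(p, 1e-300)))
    return pd.DataFrame(rows, columns=["rsid", "p"])


@dataclass
class SyntheticDataset:
    """All six pipeline inputs plus the planted ground truth."""

    config: SimulationConfig
    cohort: Cohort
    disease_snps: pd.DataFrame
    modules: list
    esnp_map: pd.DataFrame
    ld_table: pd.DataFrame
    gwas: pd.DataFrame
    planted: Planted


def simulate_all(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete, internally consistent synthetic study."""
    planted = designate_planted_genes(config)
    cohort = generate_cohort(config)
    disease_snps = pd.DataFrame(
        {
            "rsid": cohort.planted_pairs["rsid"],
            "chromosome": "1",
            "position": cohort.snp_positions[cohort.planted_pairs["rsid"]].values,
            "functional_type": "intergenic",
            "adjacent_gene": cohort.planted_pairs["gene"],
        }
    )
    modules = generate_modules(config, planted.trait_genes)
    esnp_map = generate_esnp_map(config)
    ld_table, proxy_of = generate_ld_map(esnp_map, config)
    gwas = generate_gwas_summary(esnp_map, planted.true_genes, config, proxy_of)
    return SyntheticDataset(
        config=config,
        cohort=cohort,
        disease_snps=disease_snps,
        modules=modules,
        esnp_map=esnp_map,
        ld_table=ld_table,
        gwas=gwas,
        planted=planted,
    )
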