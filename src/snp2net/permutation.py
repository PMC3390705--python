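"""Permutation null models for the enrichment fraction.

Two resampling schemes estimate how large the top-half significant fraction
would be with the disease information destroyed:

* **half_genes** — within one quantile set, draw floor(n/2) genes at random
  (ignoring delta-rank), map to eSNPs, expand LD, record the significant
  fraction.  Nulls out the delta-rank split while conditioning on the set.
* **random_traits** — redraw the initial expression traits uniformly from
  the module gene universe and rerun the entire analysis (module selection,
  scoring, ranking, exclusion, quantile split, enrichment), recording the
  top-half fraction at each cut-off.  The stricter model: it nulls the
  trait identity itself.

Empirical p-values use the add-one estimator
``(1 + #{null >= observed}) / (1 + #null)`` with ties counted against
significance, so p is never zero and is valid at any replicate count.

Each replicate draws from an independent substream ``default_rng([seed, r])``
so results do not depend on execution order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import (
    ALPHA,
    DEFAULT_CUTOFFS,
    R2_THRESHOLD,
    build_ld_index,
    expand_ld,
    fraction_significant,
    map_genes_to_esnps,
)
from .module_scoring import ScoringEngine, _rank_by_score

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationConfig",
    "PermutationResult",
    "empirical_p",
    "permute_half_genes",
    "TraitPermutationEngine",
    "permute_traits",
]


@dataclass(frozen=True)
class PermutationConfig:
    model: str = "half_genes"  # or "random_traits"
    n_reps: int = 10_000  # convention: 10,000 for half_genes, 1,000 for random_traits
    n_traits: int = 33
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("half_genes", "random_traits"):
            raise ValueError(f"unknown permutation model {self.model!r}")
        if self.n_reps < 1 or self.n_traits < 1:
            raise ValueError("n_reps and n_traits must be >= 1")


@dataclass
class PermutationResult:
    observed: float
    null_draws: np.ndarray
    empirical_p: float
    n_missing: int = 0  # replicates with no GWAS overlap, excluded from the null


def empirical_p(observed: float, null_draws) -> float:
    """Add-one empirical p-value: (1 + #{null >= observed}) / (1 + n)."""
    draws = np.asarray(null_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty null draws")
    return float((1 + np.sum(draws >= observed)) / (1 + draws.size))


def _rep_rng(seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, 7, rep])


def permute_half_genes(
    gene_set: Iterable[str],
    observed: float,
    esnp_map,
    ld_table,
    gwas: Mapping[str, float],
    config: PermutationConfig,
    alpha: float = ALPHA,
    r2_threshold: float = R2_THRESHOLD,
) -> PermutationResult:
    """Null model 1: random half-samples of one quantile gene set.

    ``observed`` is the significant fraction of the top (by delta-rank) half;
    each replicate draws floor(n/2) genes without replacement from the full
    set and recomputes the fraction through the same eSNP/LD/GWAS path.
    Replicates whose expanded SNPs miss the GWAS table entirely are recorded
    as missing and excluded from the null.
    """
    genes = sorted(set(gene_set))
    if len(genes) < 2:
        raise ValueError("gene set must contain at least 2 genes")
    if isinstance(esnp_map, pd.DataFrame):
        esnp_map = {g: tuple(sub) for g, sub in esnp_map.groupby("gene")["rsid"]}
    if isinstance(ld_table, pd.DataFrame):
        ld_table = build_ld_index(ld_table, r2_threshold)
    half = len(genes) // 2
    draws = []
    n_missing = 0
    genes_arr = np.asarray(genes, dtype=object)
    for rep in range(config.n_reps):
        rng = _rep_rng(config.seed, rep)
        sample = genes_arr[rng.choice(len(genes_arr), size=half, replace=False)]
        snps = expand_ld(map_genes_to_esnps(sample, esnp_map).snps, ld_table, r2_threshold)
        try:
            draws.append(fraction_significant(snps, gwas, alpha).fraction)
        except ValueError:
            n_missing += 1
    if n_missing:
        logger.warning("%d/%d half-sample replicates had no GWAS overlap",
                       n_missing, config.n_reps)
    null = np.asarray(draws)
    return PermutationResult(
        observed=float(observed),
        null_draws=null,
        empirical_p=empirical_p(observed, null),
        n_missing=n_missing,
    )


class TraitPermutationEngine:
    """Precomputed pipeline for repeated trait -> enrichment evaluation.

    Holds the sparse scoring engine, the gene -> eSNP map, the strong-LD
    index and the GWAS lookup so that one replicate of the random-traits
    model costs a sparse product and a handful of set unions.
    """

    def __init__(
        self,
        modules,
        esnp_map,
        ld_table,
        gwas,
        cutoff_percentiles: Sequence[float] = DEFAULT_CUTOFFS,
        alpha: float = ALPHA,
        r2_threshold: float = R2_THRESHOLD,
        adjacent_genes: Iterable[str] = (),
    ):
        self.scoring = ScoringEngine(modules)
        if isinstance(esnp_map, pd.DataFrame):
            esnp_map = {g: tuple(sub) for g, sub in esnp_map.groupby("gene")["rsid"]}
        self.esnp_map = esnp_map
        if isinstance(ld_table, pd.DataFrame):
            ld_table = build_ld_index(ld_table, r2_threshold)
        self.ld_index = ld_table
        if not isinstance(gwas, Mapping):
            gwas = dict(zip(gwas["rsid"], gwas["p"]))
        self.gwas = gwas
        self.cutoffs = tuple(cutoff_percentiles)
        self.alpha = alpha
        self.r2_threshold = r2_threshold
        self.adjacent_genes = frozenset(g for g in adjacent_genes if g)

    @property
    def gene_universe(self) -> np.ndarray:
        """All genes appearing in >= 1 module (the trait sampling universe)."""
        return self.scoring.genes

    def _fraction(self, genes: np.ndarray) -> float:
        snps = expand_ld(
            map_genes_to_esnps(genes, self.esnp_map).snps,
            self.ld_index, self.r2_threshold,
        )
        try:
            return fraction_significant(snps, self.gwas, self.alpha).fraction
        except ValueError:
            return math.nan

    def half_fractions(self, traits: Iterable[str]) -> dict:
        """Top/bottom-half significant fraction at each cut-off for one trait set.

        Runs module selection, scoring, ranking, exclusion of the traits and
        adjacent genes, quantile selection and the median delta-rank split,
        entirely on the precomputed index.  Returns
        ``{cutoff: (top_fraction, bottom_fraction)}`` with NaN where a half
        has no GWAS-covered SNP; an empty dict if no module contains a trait.
        """
        traits = set(traits)
        mask = self.scoring.module_mask_for_traits(traits)
        if not mask.any():
            return {}
        eng = self.scoring
        dscore = eng.disease_scores(mask)
        in_list = np.asarray(eng.incidence[mask].sum(axis=0)).ravel() > 0
        # ranks are assigned on the full disease list; known genes are
        # excluded afterwards, keeping the surviving genes' original ranks
        disease_rank = _rank_by_score(dscore[in_list])
        keep_sub = np.ones(int(in_list.sum()), dtype=bool)
        excluded = traits | self.adjacent_genes
        if excluded:
            keep_sub = ~np.isin(eng.genes[in_list], sorted(excluded))
        if not keep_sub.any():
            return {}
        genes = eng.genes[in_list][keep_sub]
        scores = dscore[in_list][keep_sub]
        delta = eng.background_rank[in_list][keep_sub] - disease_rank[keep_sub]
        out = {}
        for q in self.cutoffs:
            threshold = np.percentile(scores, q)
            sel = scores >= threshold
            med = np.median(delta[sel])
            top = genes[sel & (delta > med)]
            bottom = genes[sel & (delta <= med)]
            out[q] = (self._fraction(top), self._fraction(bottom))
        return out


def permute_traits(
    engine: TraitPermutationEngine,
    observed_traits: Iterable[str],
    config: PermutationConfig,
) -> dict:
    """Null model 2: redraw the initial expression traits and rerun everything.

    Each replicate samples ``config.n_traits`` genes uniformly without
    replacement from the module gene universe and records the top-half
    fraction at every cut-off; the observed statistic is the top-half
    fraction under the real traits.  Returns
    ``{cutoff: PermutationResult}``.  Replicates hitting no module, or with
    no GWAS overlap at a given cut-off, are excluded from that null with a
    warning.
    """
    observed = engine.half_fractions(observed_traits)
    if not observed:
        raise ValueError("observed traits hit no module")
    universe = engine.gene_universe
    if len(universe) < config.n_traits:
        raise ValueError("module gene universe smaller than n_traits")
    draws: dict[float, list] = {q: [] for q in engine.cutoffs}
    n_empty = 0
    for rep in range(config.n_reps):
        rng = _rep_rng(config.seed, rep)
        traits = universe[rng.choice(len(universe), size=config.n_traits, replace=False)]
        fractions = engine.half_fractions(traits)
        if not fractions:
            n_empty += 1
            continue
        for q, (top, _bottom) in fractions.items():
            if not math.isnan(top):
                draws[q].append(top)
    if n_empty:
        logger.warning("%d/%d trait replicates hit no module", n_empty, config.n_reps)
    results = {}
    for q in engine.cutoffs:
        null = np.asarray(draws[q])
        obs = observed[q][0]
        results[q] = PermutationResult(
            observed=float(obs),
            null_draws=null,
            empirical_p=empirical_p(obs, null),
            n_missing=config.n_reps - null.size,
        )
    return results
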