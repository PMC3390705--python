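"""Genetic validation of candidate genes by GWAS eSNP enrichment.

High-scoring genes are mapped back to their genome-wide-significant eSNPs,
the eSNP set is expanded with LD proxies (R^2 strictly above a threshold,
default 0.8, bridging genotyping platforms), and the fraction of those SNPs
with GWAS association p below alpha (default 0.05) is recorded.  Candidate
sets are formed at disease-score quantile cut-offs and each set is split at
its median rank difference: if the score and delta-rank carry disease
information, the above-median half should be more enriched than the
below-median half — that comparison is what the permutation module tests.

Known genes (the expression traits themselves and genes adjacent to the
disease SNPs) are removed first, so enrichment is measured on novel
candidates only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "exclude_known",
    "quantile_split",
    "QuantileSet",
    "map_genes_to_esnps",
    "EsnpMapping",
    "build_ld_index",
    "expand_ld",
    "fraction_significant",
    "FractionResult",
    "enrichment_table",
]

R2_THRESHOLD = 0.8
ALPHA = 0.05
DEFAULT_CUTOFFS = (0.0, 75.0, 90.0, 95.0, 97.5, 99.0)


def exclude_known(
    score_table: pd.DataFrame,
    traits: Iterable[str] = (),
    adjacent_genes: Iterable[str] = (),
) -> pd.DataFrame:
    """Drop expression traits and disease-SNP-adjacent genes from the table."""
    known = set(traits) | {g for g in adjacent_genes if g}
    return score_table[~score_table["gene"].isin(known)].reset_index(drop=True)


@dataclass(frozen=True)
class QuantileSet:
    """Genes above one disease-score quantile, split at the median delta-rank."""

    cutoff: float
    selected: frozenset
    top: frozenset  # delta_rank strictly above the median
    bottom: frozenset  # delta_rank at or below the median
    median_delta: float


def quantile_split(
    score_table: pd.DataFrame,
    cutoff_percentiles: Sequence[float] = DEFAULT_CUTOFFS,
) -> list[QuantileSet]:
    """Candidate gene sets at each disease-score percentile cut-off.

    For percentile q the set is the genes whose disease score is at or above
    the q-th percentile of the score distribution (linear interpolation);
    the set is then split at its own median delta-rank, strictly-above going
    to the top half and ties-at-median to the bottom half.
    """
    if score_table.empty:
        raise ValueError("empty score table")
    scores = score_table["disease_score"].to_numpy(dtype=float)
    deltas = score_table["delta_rank"].to_numpy(dtype=float)
    genes = score_table["gene"].to_numpy(dtype=object)
    out = []
    for q in cutoff_percentiles:
        if not (0 <= q < 100):
            raise ValueError(f"cutoff percentile {q} outside [0, 100)")
        threshold = np.percentile(scores, q)
        mask = scores >= threshold
        med = float(np.median(deltas[mask]))
        top = mask & (deltas > med)
        bottom = mask & (deltas <= med)
        out.append(
            QuantileSet(
                cutoff=float(q),
                selected=frozenset(genes[mask]),
                top=frozenset(genes[top]),
                bottom=frozenset(genes[bottom]),
                median_delta=med,
            )
        )
    return out


@dataclass(frozen=True)
class EsnpMapping:
    snps: frozenset
    unmapped_genes: frozenset  # genes with no genome-wide-significant eSNP


def map_genes_to_esnps(genes: Iterable[str], esnp_map) -> EsnpMapping:
    """Union of the genes' genome-wide-significant eSNPs (deduplicated).

    ``esnp_map`` is either a DataFrame with ``gene``/``rsid`` columns or a
    prebuilt ``gene -> iterable of rsids`` mapping.  Genes absent from the
    map contribute nothing and are reported in ``unmapped_genes``.
    """
    if isinstance(esnp_map, pd.DataFrame):
        esnp_map = {g: tuple(sub) for g, sub in esnp_map.groupby("gene")["rsid"]}
    snps: set = set()
    unmapped = []
    for g in genes:
        hit = esnp_map.get(g)
        if hit:
            snps.update(hit)
        else:
            unmapped.append(g)
    return EsnpMapping(snps=frozenset(snps), unmapped_genes=frozenset(unmapped))


def build_ld_index(ld_table: pd.DataFrame, r2_threshold: float = R2_THRESHOLD) -> dict:
    """Adjacency of LD partners with R^2 strictly above the threshold.

    The pair table stores each unordered pair once; the index is symmetric.
    """
    if not (0 <= r2_threshold <= 1):
        raise ValueError("r2_threshold must lie in [0, 1]")
    strong = ld_table[ld_table["r2"] > r2_threshold]
    index: dict[str, set] = {}
    for a, b in zip(strong["rsid_a"], strong["rsid_b"]):
        index.setdefault(a, set()).add(b)
        index.setdefault(b, set()).add(a)
    return index


def expand_ld(snps: Iterable[str], ld, r2_threshold: float = R2_THRESHOLD) -> frozenset:
    """Add direct strong-LD partners of the input SNPs (single step).

    ``ld`` may be the pair DataFrame or an index from :func:`build_ld_index`.
    Expansion is one hop only — partners of partners are *not* pulled in —
    and the output always contains the input.
    """
    if isinstance(ld, pd.DataFrame):
        ld = build_ld_index(ld, r2_threshold)
    snps = set(snps)
    expanded = set(snps)
    for s in snps:
        expanded.update(ld.get(s, ()))
    return frozenset(expanded)


@dataclass(frozen=True)
class FractionResult:
    fraction: float
    n_tested: int
    n_significant: int
    n_missing: int  # SNPs absent from the GWAS table


def fraction_significant(
    snps: Iterable[str], gwas: Mapping[str, float], alpha: float = ALPHA
) -> FractionResult:
    """Fraction of SNPs with GWAS p strictly below alpha.

    SNPs absent from the GWAS table are dropped from both numerator and
    denominator (different platforms overlap incompletely) and counted in
    ``n_missing``.  Duplicate inputs collapse (set semantics).  Raises if no
    SNP overlaps the GWAS table.
    """
    tested = []
    missing = 0
    for s in set(snps):
        p = gwas.get(s)
        if p is None:
            missing += 1
        else:
            tested.append(p)
    if not tested:
        raise ValueError("no overlapping SNPs between the input set and the GWAS table")
    n_sig = int(np.sum(np.asarray(tested) < alpha))
    return FractionResult(
        fraction=n_sig / len(tested),
        n_tested=len(tested),
        n_significant=n_sig,
        n_missing=missing,
    )


def enrichment_table(
    score_table: pd.DataFrame,
    esnp_map,
    ld_table,
    gwas: Mapping[str, float],
    cutoff_percentiles: Sequence[float] = DEFAULT_CUTOFFS,
    alpha: float = ALPHA,
    r2_threshold: float = R2_THRESHOLD,
) -> pd.DataFrame:
    """Per (cutoff, half) enrichment of GWAS significance.

    Convenience wrapper chaining quantile split -> eSNP mapping -> LD
    expansion -> significant fraction; rows with no GWAS overlap get NaN.
    """
    if isinstance(esnp_map, pd.DataFrame):
        esnp_map = {g: tuple(sub) for g, sub in esnp_map.groupby("gene")["rsid"]}
    if isinstance(ld_table, pd.DataFrame):
        ld_table = build_ld_index(ld_table, r2_threshold)
    if not isinstance(gwas, Mapping):
        gwas = dict(zip(gwas["rsid"], gwas["p"]))
    rows = []
    for qs in quantile_split(score_table, cutoff_percentiles):
        for half, genes in (("top", qs.top), ("bottom", qs.bottom)):
            mapping = map_genes_to_esnps(genes, esnp_map)
            expanded = expand_ld(mapping.snps, ld_table, r2_threshold)
            try:
                frac = fraction_significant(expanded, gwas, alpha)
                fraction, n_tested = frac.fraction, frac.n_tested
            except ValueError:
                logger.warning(
                    "cutoff %s %s half: no GWAS overlap", qs.cutoff, half
                )
                fraction, n_tested = float("nan"), 0
            rows.append(
                (qs.cutoff, half, len(genes), len(mapping.snps), len(expanded),
                 n_tested, fraction)
            )
    return pd.DataFrame(
        rows,
        columns=["cutoff", "half", "n_genes", "n_esnps", "n_expanded",
                 "n_tested", "fraction_significant"],
    )
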