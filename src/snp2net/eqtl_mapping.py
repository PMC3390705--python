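"""Disease SNP -> expression trait mapping via cis association.

A disease SNP's candidate functional readouts are the genes whose expression
differs across its genotype classes.  Association is tested with the
Kruskal-Wallis rank test (robust to the expression noise family, invariant
under monotone transforms), restricted to genes within a cis window
(default 1 Mb) of the SNP, at an uncorrected p-value cut-off (default 0.05):
the relaxed threshold is deliberate, since downstream genetic validation
filters false positives.

Alternatively a precomputed cis-eQTL association table may be supplied, in
which case its p-values are trusted and the test is bypassed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["KruskalWallisResult", "kruskal_wallis", "map_cis_traits", "TraitMapping"]

CIS_WINDOW = 1_000_000
P_CUT = 0.05


@dataclass(frozen=True)
class KruskalWallisResult:
    h_statistic: float
    k_groups: int
    p_value: float


def kruskal_wallis(genotypes, expression) -> KruskalWallisResult:
    """Kruskal-Wallis test of expression across genotype classes.

    ``genotypes`` holds per-individual allele counts in {0, 1, 2};
    ``expression`` the matched real-valued measurements.  Classes with zero
    members are dropped and the chi-square degrees of freedom reduced
    accordingly.  H is tie-corrected; if every expression value is equal the
    tie correction degenerates and the result is H = 0, p = 1 by convention.

    Raises ``ValueError`` for mismatched lengths or a monomorphic SNP
    (fewer than two genotype classes present).
    """
    g = np.asarray(genotypes)
    x = np.asarray(expression, dtype=float)
    if g.shape != x.shape or g.ndim != 1:
        raise ValueError("genotype and expression vectors must be 1-D and equal length")
    classes = np.unique(g)
    if classes.size < 2:
        raise ValueError("monomorphic SNP: fewer than two genotype classes")
    groups = [x[g == c] for c in classes]
    if np.all(x == x[0]):
        return KruskalWallisResult(0.0, int(classes.size), 1.0)
    h, p = stats.kruskal(*groups)
    return KruskalWallisResult(float(h), int(classes.size), float(min(p, 1.0)))


@dataclass
class TraitMapping:
    """Result of cis trait mapping plus the bookkeeping the report needs."""

    traits: pd.DataFrame  # columns rsid, gene, tissue, p
    snps_without_traits: list = field(default_factory=list)
    snps_skipped: list = field(default_factory=list)  # unknown position / monomorphic

    @property
    def trait_genes(self) -> set:
        return set(self.traits["gene"])

    @property
    def mapped_snps(self) -> set:
        return set(self.traits["rsid"])


def _traits_from_table(disease_snps, eqtl_table, window, p_cut) -> pd.DataFrame:
    required = {"rsid", "gene", "p_value"}
    missing = required - set(eqtl_table.columns)
    if missing:
        raise ValueError(f"eQTL table missing columns: {sorted(missing)}")
    t = eqtl_table[eqtl_table["rsid"].isin(set(disease_snps["rsid"]))].copy()
    if "distance" in t.columns:
        dist = t["distance"]
    elif {"snp_pos", "gene_pos"} <= set(t.columns):
        dist = (t["snp_pos"] - t["gene_pos"]).abs()
    else:
        raise ValueError("eQTL table needs a distance or snp_pos/gene_pos columns")
    t = t[(dist <= window) & (t["p_value"] < p_cut)]
    if "tissue" not in t.columns:
        t = t.assign(tissue="unknown")
    return t.rename(columns={"p_value": "p"})[["rsid", "gene", "tissue", "p"]]


def _traits_from_matrices(
    disease_snps, genotypes, expression, snp_positions, gene_positions,
    window, p_cut, tissue, skipped,
) -> pd.DataFrame:
    gene_pos = gene_positions.sort_values()
    rows = []
    for snp in disease_snps.itertuples(index=False):
        rsid = snp.rsid
        pos = snp_positions.get(rsid, getattr(snp, "position", None))
        if pos is None or pd.isna(pos):
            logger.warning("disease SNP %s has no known position; skipped", rsid)
            skipped.append(rsid)
            continue
        if rsid not in genotypes.columns:
            logger.warning("disease SNP %s absent from genotype matrix; skipped", rsid)
            skipped.append(rsid)
            continue
        g = genotypes[rsid].to_numpy()
        lo, hi = np.searchsorted(gene_pos.values, [pos - window, pos + window + 1])
        for gene in gene_pos.index[lo:hi]:
            if gene not in expression.columns:
                continue
            try:
                res = kruskal_wallis(g, expression[gene].to_numpy())
            except ValueError:
                skipped.append(rsid)
                break
            if res.p_value < p_cut:
                rows.append((rsid, gene, tissue, res.p_value))
    return pd.DataFrame(rows, columns=["rsid", "gene", "tissue", "p"])


def map_cis_traits(
    disease_snps: pd.DataFrame,
    eqtl_table: pd.DataFrame | None = None,
    *,
    genotypes: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
    snp_positions: pd.Series | None = None,
    gene_positions: pd.Series | None = None,
    window: int = CIS_WINDOW,
    p_cut: float = P_CUT,
    tissue: str = "expression",
) -> TraitMapping:
    """Map disease SNPs to their cis expression traits.

    Either ``eqtl_table`` (columns rsid, gene, p_value, optional tissue and
    distance or snp_pos/gene_pos) or the full matrix inputs must be given.
    A gene qualifies as an expression trait of a SNP if their distance is at
    most ``window`` (boundary inclusive) and the association p-value is
    strictly below ``p_cut`` in any tissue.  SNPs yielding no trait are
    reported in ``snps_without_traits``; SNPs with unknown position (or a
    monomorphic genotype column) are skipped and reported.
    """
    skipped: list = []
    if eqtl_table is not None:
        traits = _traits_from_table(disease_snps, eqtl_table, window, p_cut)
    else:
        if genotypes is None or expression is None:
            raise ValueError("need either an eQTL table or genotype+expression matrices")
        if snp_positions is None:
            snp_positions = pd.Series(dtype=np.int64)
        if gene_positions is None:
            raise ValueError("gene_positions required for the matrix path")
        traits = _traits_from_matrices(
            disease_snps, genotypes, expression, snp_positions, gene_positions,
            window, p_cut, tissue, skipped,
        )
    traits = traits.sort_values(["rsid", "gene", "tissue"], ignore_index=True)
    mapped = set(traits["rsid"])
    dropped = sorted(set(disease_snps["rsid"]) - mapped - set(skipped))
    if dropped:
        logger.info("%d disease SNPs had no qualifying cis trait", len(dropped))
    return TraitMapping(
        traits=traits, snps_without_traits=dropped, snps_skipped=sorted(set(skipped))
    )
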