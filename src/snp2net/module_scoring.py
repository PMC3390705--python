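"""Coexpression-module co-occurrence scoring.

A gene that keeps turning up in the disease-selected coexpression modules is
a candidate for involvement in the disease process, but membership of a large
module is cheap.  The score used here therefore weights each co-occurrence by
the inverse of the module size:

    score(g) = sum_i 1 / S_i    over modules i containing g,

where ``S_i`` is the number of genes in module *i*.  Two scores are computed
for every gene: the *disease* score, summed over the modules that contain at
least one disease expression trait, and the *background* score, summed over
the whole module collection.  Genes are ranked (1 = highest score) within
each list and the rank difference

    delta_rank = background_rank - disease_rank

flags genes that are far more prominent in the disease context than overall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "CoexpressionModule",
    "select_disease_modules",
    "inverse_sum_score",
    "score_and_rank",
    "ScoringEngine",
]


@dataclass(frozen=True)
class CoexpressionModule:
    """A named gene set from one tissue/cross coexpression network."""

    module_id: str
    source: str
    genes: frozenset

    def __post_init__(self):
        if len(self.genes) < 1:
            raise ValueError(f"module {self.module_id!r} is empty")

    @property
    def size(self) -> int:
        return len(self.genes)


def select_disease_modules(
    modules: Sequence[CoexpressionModule], traits: Iterable[str]
) -> tuple[list[CoexpressionModule], set]:
    """Modules containing at least one expression trait.

    Returns the selected modules and the subset of ``traits`` found in at
    least one module.  An empty selection is allowed (the caller decides
    whether that is fatal).
    """
    trait_set = set(traits)
    selected = [m for m in modules if m.genes & trait_set]
    present = set().union(*(m.genes & trait_set for m in selected)) if selected else set()
    return selected, present


def inverse_sum_score(gene: str, modules: Iterable[CoexpressionModule]) -> float:
    """Sum of 1/S_i over the given modules containing ``gene`` (0 if none)."""
    return float(sum(1.0 / m.size for m in modules if gene in m.genes))


def _rank_by_score(scores: np.ndarray) -> np.ndarray:
    """Dense 1-based ranks, highest score first.

    Ties are broken by position in the (alphabetically pre-sorted) gene
    array, so equal scores get strictly sequential ranks in lexicographic
    gene order and the result is reproducible.
    """
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty(len(scores), dtype=np.int64)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


class ScoringEngine:
    """Pre-indexed module collection for repeated scoring runs.

    Builds a sparse module x gene incidence matrix once; the background
    score and rank never change, while disease scores for an arbitrary trait
    set are a single sparse matrix-vector product.  The trait-permutation
    null model reruns scoring thousands of times, which is why this exists.
    """

    def __init__(self, modules: Sequence[CoexpressionModule]):
        if not modules:
            raise ValueError("no modules")
        self.modules = list(modules)
        universe = sorted(set().union(*(m.genes for m in self.modules)))
        self.genes = np.asarray(universe, dtype=object)
        self._gene_idx = {g: i for i, g in enumerate(universe)}
        rows, cols = [], []
        for i, m in enumerate(self.modules):
            for g in m.genes:
                rows.append(i)
                cols.append(self._gene_idx[g])
        data = np.ones(len(rows), dtype=np.float64)
        self.incidence = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(self.modules), len(universe))
        )
        self._incidence_csc = self.incidence.tocsc()
        self.sizes = np.asarray([m.size for m in self.modules], dtype=np.float64)
        self.inv_sizes = 1.0 / self.sizes
        self.background_score = self.inv_sizes @ self.incidence
        self.background_rank = _rank_by_score(self.background_score)

    def module_mask_for_traits(self, traits: Iterable[str]) -> np.ndarray:
        """Boolean mask over modules: contains >= 1 of the given genes."""
        idx = [self._gene_idx[t] for t in traits if t in self._gene_idx]
        if not idx:
            return np.zeros(len(self.modules), dtype=bool)
        hits = self._incidence_csc[:, idx].sum(axis=1)
        return np.asarray(hits).ravel() > 0

    def disease_scores(self, module_mask: np.ndarray) -> np.ndarray:
        """Inverse-sum score over the masked modules, for every gene."""
        w = np.where(module_mask, self.inv_sizes, 0.0)
        return w @ self.incidence

    def score_frame(self, module_mask: np.ndarray) -> pd.DataFrame:
        """Full per-gene score/rank table for one disease-module selection.

        Only genes appearing in at least one selected module get a record;
        their disease rank is computed within that restricted list while the
        background rank is the gene's rank in the full background list.
        """
        if not module_mask.any():
            raise ValueError("no disease modules")
        dscore = self.disease_scores(module_mask)
        in_list = np.asarray(
            (self.incidence[module_mask].sum(axis=0)).ravel() > 0
        ).ravel()
        genes = self.genes[in_list]
        dscore_sub = dscore[in_list]
        disease_rank = _rank_by_score(dscore_sub)
        background_rank = self.background_rank[in_list]
        frame = pd.DataFrame(
            {
                "gene": genes,
                "disease_score": dscore_sub,
                "background_score": self.background_score[in_list],
                "disease_rank": disease_rank,
                "background_rank": background_rank,
            }
        )
        frame["delta_rank"] = frame["background_rank"] - frame["disease_rank"]
        # each selected module of size S contributes S * 1/S = 1 to the total
        n_sel = int(module_mask.sum())
        total = float(dscore_sub.sum())
        if abs(total - n_sel) > 1e-9:
            raise AssertionError(
                f"disease score mass {total!r} != {n_sel} selected modules"
            )
        bg_total = float(self.background_score.sum())
        if abs(bg_total - len(self.modules)) > 1e-9:
            raise AssertionError(
                f"background score mass {bg_total!r} != {len(self.modules)} modules"
            )
        return frame.sort_values("disease_rank", ignore_index=True)


def score_and_rank(
    modules: Sequence[CoexpressionModule],
    disease_modules: Sequence[CoexpressionModule],
) -> pd.DataFrame:
    """Score every gene against the disease and background module sets.

    ``disease_modules`` must be a subset of ``modules``.  Returns one row per
    gene present in at least one disease module, with columns ``gene``,
    ``disease_score``, ``background_score``, ``disease_rank``,
    ``background_rank`` and ``delta_rank``, sorted by disease rank.
    """
    if not disease_modules:
        raise ValueError("no disease modules")
    ids = {id(m) for m in modules}
    if any(id(m) not in ids for m in disease_modules):
        # allow value-equal modules supplied as a fresh list
        mods = set(modules)
        if any(m not in mods for m in disease_modules):
            raise ValueError("disease_modules must be a subset of modules")
    engine = ScoringEngine(modules)
    mask = np.zeros(len(engine.modules), dtype=bool)
    by_identity = {id(m): i for i, m in enumerate(engine.modules)}
    matched = [by_identity.get(id(m)) for m in disease_modules]
    if any(i is None for i in matched):
        by_value = {}
        for i, m in enumerate(engine.modules):
            by_value.setdefault(m, i)
        matched = [by_value[m] for m in disease_modules]
    mask[np.asarray(matched, dtype=int)] = True
    return engine.score_frame(mask)
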