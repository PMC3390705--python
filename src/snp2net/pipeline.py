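"""End-to-end orchestration: simulate / map-traits / score / enrich / permute.

``run_all`` chains the full analysis from files on disk — disease SNPs ->
cis expression traits -> disease module selection -> inverse-sum scoring and
ranking -> exclusion of known genes -> quantile/delta-rank enrichment ->
both permutation null models — and writes every stage table plus a
machine-readable ``summary.txt`` of stage counts.  The summary is a pure
function of the inputs and the seed, so two runs that differ only in output
directory produce byte-identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .enrichment import (
    ALPHA,
    DEFAULT_CUTOFFS,
    R2_THRESHOLD,
    enrichment_table,
    exclude_known,
    quantile_split,
)
from .eqtl_mapping import CIS_WINDOW, P_CUT, map_cis_traits
from .module_scoring import score_and_rank, select_disease_modules
from .permutation import (
    PermutationConfig,
    TraitPermutationEngine,
    permute_half_genes,
    permute_traits,
)
from .synthetic_data import SimulationConfig, SyntheticDataset, simulate_all

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "write_dataset", "simulate_to_dir"]


@dataclass
class PipelineConfig:
    """Paths and parameters for one full pipeline run."""

    snps_path: str
    modules_paths: Sequence[str]
    esnp_map_path: str
    ld_path: str
    gwas_path: str
    out_dir: str
    # either a precomputed eQTL association table ...
    eqtl_path: str | None = None
    # ... or raw matrices plus coordinate tables
    genotypes_path: str | None = None
    expression_path: str | None = None
    snp_positions_path: str | None = None
    gene_positions_path: str | None = None

    window: int = CIS_WINDOW
    p_cut: float = P_CUT
    alpha: float = ALPHA
    r2_threshold: float = R2_THRESHOLD
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS
    perm_half_reps: int = 10_000
    perm_trait_reps: int = 1_000
    n_traits: int | None = None  # default: number of traits found in modules
    seed: int = 0

    def __post_init__(self):
        if self.eqtl_path is None and (
            self.genotypes_path is None or self.expression_path is None
        ):
            raise ValueError(
                "config needs eqtl_path or genotypes_path+expression_path"
            )
        if not (0 < self.p_cut < 1) or not (0 < self.alpha < 1):
            raise ValueError("p_cut and alpha must lie in (0, 1)")
        if not (0 <= self.r2_threshold <= 1):
            raise ValueError("r2_threshold must lie in [0, 1]")
        if self.window <= 0:
            raise ValueError("window must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(self).items()},
                fh, sort_keys=True,
            )


def _summary_lines(report: dict) -> str:
    lines = []
    for key in sorted(report):
        value = report[key]
        if isinstance(value, float):
            value = f"{value:.10g}"
        lines.append(f"{key}\t{value}")
    return "\n".join(lines) + "\n"


def run_all(config: PipelineConfig) -> dict:
    """Execute the full chain and write all stage outputs.

    Returns the summary report (stage counts, per-cutoff enrichment
    fractions and permutation p-values).  Raises on validation failures
    only; statistically null results are a valid outcome.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    disease_snps = sio.read_disease_snps(config.snps_path)
    modules = sio.read_modules(config.modules_paths)
    esnp_map = sio.read_esnp_map(config.esnp_map_path)
    ld_table = sio.read_ld_table(config.ld_path)
    gwas = sio.gwas_to_dict(sio.read_gwas(config.gwas_path))

    # 1. cis expression traits
    if config.eqtl_path is not None:
        mapping = map_cis_traits(
            disease_snps, sio.read_eqtl_table(config.eqtl_path),
            window=config.window, p_cut=config.p_cut,
        )
    else:
        snp_pos = sio.read_matrix(config.snp_positions_path)["position"] \
            if config.snp_positions_path else None
        gene_pos = sio.read_matrix(config.gene_positions_path)["position"]
        mapping = map_cis_traits(
            disease_snps,
            genotypes=sio.read_matrix(config.genotypes_path),
            expression=sio.read_matrix(config.expression_path),
            snp_positions=snp_pos,
            gene_positions=gene_pos,
            window=config.window, p_cut=config.p_cut,
        )
    sio.write_tsv(mapping.traits, out / "traits.tsv")
    traits = mapping.trait_genes

    # 2. disease modules, scoring, ranking
    disease_modules, traits_in_modules = select_disease_modules(modules, traits)
    if not disease_modules:
        raise ValueError("pipeline stage module_scoring: no disease modules selected")
    scores = score_and_rank(modules, disease_modules)
    sio.write_tsv(scores, out / "score_table.tsv")

    # 3. exclusion + enrichment
    adjacent = set(disease_snps["adjacent_gene"]) - {""}
    candidates = exclude_known(scores, traits, adjacent)
    enrich = enrichment_table(
        candidates, esnp_map, ld_table, gwas,
        cutoff_percentiles=config.cutoffs, alpha=config.alpha,
        r2_threshold=config.r2_threshold,
    )
    sio.write_tsv(enrich, out / "enrichment.tsv")

    # 4. permutations
    perm_rows = []
    observed = {
        (row.cutoff, row.half): row.fraction_significant
        for row in enrich.itertuples(index=False)
    }
    splits = quantile_split(candidates, config.cutoffs)
    for qs in splits:
        obs = observed[(qs.cutoff, "top")]
        if np.isnan(obs) or len(qs.selected) < 2:
            continue
        res = permute_half_genes(
            qs.selected, obs, esnp_map, ld_table, gwas,
            PermutationConfig(model="half_genes", n_reps=config.perm_half_reps,
                              seed=config.seed),
            alpha=config.alpha, r2_threshold=config.r2_threshold,
        )
        perm_rows.append((qs.cutoff, "half_genes", res.observed, res.empirical_p,
                          res.null_draws.size, res.n_missing))

    n_traits = config.n_traits or max(len(traits_in_modules), 1)
    engine = TraitPermutationEngine(
        modules, esnp_map, ld_table, gwas,
        cutoff_percentiles=config.cutoffs, alpha=config.alpha,
        r2_threshold=config.r2_threshold, adjacent_genes=adjacent,
    )
    trait_results = permute_traits(
        engine, traits,
        PermutationConfig(model="random_traits", n_reps=config.perm_trait_reps,
                          n_traits=n_traits, seed=config.seed),
    )
    for q, res in sorted(trait_results.items()):
        perm_rows.append((q, "random_traits", res.observed, res.empirical_p,
                          res.null_draws.size, res.n_missing))
    permutation_out = pd.DataFrame(
        perm_rows,
        columns=["cutoff", "model", "observed", "empirical_p", "n_reps", "n_missing"],
    )
    sio.write_tsv(permutation_out, out / "permutation.tsv")

    # 5. summary
    report: dict = {
        "n_disease_snps_in": len(disease_snps),
        "n_snps_with_traits": len(mapping.mapped_snps),
        "n_snps_skipped": len(mapping.snps_skipped),
        "n_expression_traits": len(traits),
        "n_traits_in_modules": len(traits_in_modules),
        "n_modules_total": len(modules),
        "n_disease_modules": len(disease_modules),
        "n_genes_scored": len(scores),
        "n_genes_after_exclusion": len(candidates),
        "n_trait_permutation_draws": config.perm_trait_reps,
        "seed": config.seed,
    }
    for row in enrich.itertuples(index=False):
        key = f"fraction_sig_{row.half}_q{row.cutoff:g}"
        report[key] = float(row.fraction_significant)
        report[f"n_tested_{row.half}_q{row.cutoff:g}"] = int(row.n_tested)
    for row in permutation_out.itertuples(index=False):
        report[f"empirical_p_{row.model}_q{row.cutoff:g}"] = float(row.empirical_p)
    (out / "summary.txt").write_text(_summary_lines(report))
    return report


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict:
    """Write every table of a synthetic dataset in its external format.

    Returns the path map; the files are exactly what ``run_all`` consumes,
    so round-tripping a simulation through disk exercises all parsers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "snps": out / "disease_snps.tsv",
        "modules": out / "modules.gmt",
        "esnp_map": out / "esnp_map.tsv",
        "ld": out / "ld.tsv",
        "gwas": out / "gwas.tsv",
        "genotypes": out / "genotypes.tsv",
        "expression": out / "expression.tsv",
        "snp_positions": out / "snp_positions.tsv",
        "gene_positions": out / "gene_positions.tsv",
    }
    sio.write_tsv(dataset.disease_snps, paths["snps"])
    sio.write_modules(dataset.modules, paths["modules"])
    sio.write_tsv(dataset.esnp_map, paths["esnp_map"])
    sio.write_tsv(dataset.ld_table, paths["ld"])
    sio.write_tsv(dataset.gwas, paths["gwas"])
    sio.write_matrix(dataset.cohort.genotypes, paths["genotypes"])
    sio.write_matrix(dataset.cohort.expression, paths["expression"])
    sio.write_matrix(dataset.cohort.snp_positions.to_frame(), paths["snp_positions"])
    sio.write_matrix(dataset.cohort.gene_positions.to_frame(), paths["gene_positions"])
    return {k: str(v) for k, v in paths.items()}


def simulate_to_dir(sim_config: SimulationConfig, out_dir, **pipeline_kwargs) -> PipelineConfig:
    """Simulate a dataset, write it, and return a ready PipelineConfig."""
    dataset = simulate_all(sim_config)
    paths = write_dataset(dataset, out_dir)
    return PipelineConfig(
        snps_path=paths["snps"],
        modules_paths=[paths["modules"]],
        esnp_map_path=paths["esnp_map"],
        ld_path=paths["ld"],
        gwas_path=paths["gwas"],
        genotypes_path=paths["genotypes"],
        expression_path=paths["expression"],
        snp_positions_path=paths["snp_positions"],
        gene_positions_path=paths["gene_positions"],
        out_dir=str(Path(out_dir) / "results"),
        seed=sim_config.seed,
        **pipeline_kwargs,
    )
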