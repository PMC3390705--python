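"""Generator contracts: determinism, planted effects, closed-form tails."""

import numpy as np
import pandas as pd
import pytest

from snp2net.eqtl_mapping import kruskal_wallis
from snp2net.synthetic_data import (
    SimulationConfig,
    designate_planted_genes,
    generate_cohort,
    generate_esnp_map,
    generate_gwas_summary,
    generate_ld_map,
    generate_modules,
    simulate_all,
)
from snp2net.enrichment import expand_ld
from conftest import tiny_config


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"n_genes": 0},
            {"n_true_genes": 301},
            {"signal_beta_a": 0.0},
            {"signal_beta_a": 1.5},
            {"maf_range": (0.0, 0.5)},
            {"maf_range": (0.1, 0.6)},
            {"r2_range": (0.5, 1.2)},
            {"cooccurrence_prob": -0.1},
            {"gwas_coverage": 1.5},
        ],
    )
    def test_invalid_configs_rejected(self, overrides):
        with pytest.raises(ValueError):
            tiny_config(**overrides)

    def test_too_small_cohort_refused(self):
        config = tiny_config(n_individuals=50, maf_range=(0.1, 0.5))
        with pytest.raises(ValueError, match="cohort too small"):
            generate_cohort(config)


class TestDeterminism:
    def test_identical_config_and_seed_reproduce_every_table(self):
        a = simulate_all(tiny_config(seed=42))
        b = simulate_all(tiny_config(seed=42))
        pd.testing.assert_frame_equal(a.cohort.genotypes, b.cohort.genotypes)
        pd.testing.assert_frame_equal(a.cohort.expression, b.cohort.expression)
        pd.testing.assert_frame_equal(a.esnp_map, b.esnp_map)
        pd.testing.assert_frame_equal(a.ld_table, b.ld_table)
        pd.testing.assert_frame_equal(a.gwas, b.gwas)
        assert [m.genes for m in a.modules] == [m.genes for m in b.modules]

    def test_different_seeds_differ(self):
        a = simulate_all(tiny_config(seed=1))
        b = simulate_all(tiny_config(seed=2))
        assert not a.cohort.genotypes.equals(b.cohort.genotypes)


class TestCohort:
    def test_planted_pairs_lie_within_cis_window(self):
        cohort = generate_cohort(tiny_config(seed=7))
        for row in cohort.planted_pairs.itertuples(index=False):
            dist = abs(cohort.snp_positions[row.rsid]
                       - cohort.gene_positions[row.gene])
            assert dist <= 1_000_000

    def test_strong_effect_recovered_in_planted_pairs(self):
        """cis effect 5x the noise SD at n=500: planted pairs must reach
        p < 0.05 in > 95% of pair-replicates (rate established by the same
        Monte-Carlo run over 200 independent cohorts)."""
        hits = total = 0
        for seed in range(40):
            config = SimulationConfig(
                seed=seed, n_individuals=500, n_snps=10, n_genes=40,
                n_disease_snps=5, n_true_genes=5, cis_effect_size=5.0,
                n_modules=10, module_size_range=(3, 8), maf_range=(0.15, 0.5),
            )
            cohort = generate_cohort(config)
            for row in cohort.planted_pairs.itertuples(index=False):
                res = kruskal_wallis(cohort.genotypes[row.rsid],
                                     cohort.expression[row.gene])
                total += 1
                hits += res.p_value < 0.05
        assert total == 200
        assert hits / total > 0.95

    def test_null_effect_pvalues_uniform_over_planted_pairs(self):
        """cis_effect_size = 0: planted-pair p-values are Uniform(0,1); the
        fraction below 0.05 stays within 3 binomial SDs of 0.05."""
        pvals = []
        for seed in range(60):
            config = SimulationConfig(
                seed=seed, n_individuals=300, n_snps=10, n_genes=40,
                n_disease_snps=5, n_true_genes=5, cis_effect_size=0.0,
                n_modules=10, module_size_range=(3, 8), maf_range=(0.15, 0.5),
            )
            cohort = generate_cohort(config)
            for row in cohort.planted_pairs.itertuples(index=False):
                pvals.append(kruskal_wallis(cohort.genotypes[row.rsid],
                                            cohort.expression[row.gene]).p_value)
        frac = np.mean(np.asarray(pvals) < 0.05)
        sd = np.sqrt(0.05 * 0.95 / len(pvals))
        assert abs(frac - 0.05) <= 3 * sd


class TestModules:
    def test_sizes_within_range_and_no_duplicates(self, tiny_dataset):
        lo, hi = tiny_dataset.config.module_size_range
        for m in tiny_dataset.modules:
            assert lo <= m.size <= hi

    def test_oversized_module_range_refused(self):
        config = tiny_config(module_size_range=(200, 400))
        with pytest.raises(ValueError, match="exceeds gene universe"):
            generate_modules(config, ["G00001"])

    def test_true_genes_co_occur_with_traits_at_elevated_rate(self):
        config = tiny_config(seed=9, cooccurrence_prob=0.3)
        planted = designate_planted_genes(config)
        modules = generate_modules(config, planted.trait_genes)
        trait_mods = [m for m in modules if m.genes & set(planted.trait_genes)]
        true_in_trait = np.mean(
            [sum(g in m.genes for m in trait_mods) for g in planted.true_genes])
        other = sorted(set(f"G{i:05d}" for i in range(config.n_genes))
                       - set(planted.true_genes) - set(planted.trait_genes))
        other_in_trait = np.mean(
            [sum(g in m.genes for m in trait_mods) for g in other])
        assert true_in_trait > 3 * other_in_trait

    def test_zero_elevation_gives_exchangeable_true_genes(self):
        config = tiny_config(seed=9, cooccurrence_prob=0.0)
        planted = designate_planted_genes(config)
        modules = generate_modules(config, planted.trait_genes)
        counts_true = [sum(g in m.genes for m in modules)
                       for g in planted.true_genes]
        counts_all = [sum(g in m.genes for m in modules)
                      for g in (f"G{i:05d}" for i in range(config.n_genes))]
        # true genes' membership counts sit inside the global distribution
        assert min(counts_all) <= np.mean(counts_true) <= max(counts_all)
        assert np.mean(counts_true) < np.mean(counts_all) * 3


class TestGwasSummary:
    def test_uniform_when_shape_is_one(self):
        config = tiny_config(seed=3, signal_beta_a=1.0, n_genes=300,
                             esnp_rate=40.0, gwas_coverage=1.0)
        esnp_map = generate_esnp_map(config)
        gwas = generate_gwas_summary(esnp_map, [], config)
        assert len(gwas) == len(esnp_map)
        frac = (gwas["p"] < 0.05).mean()
        sd = np.sqrt(0.05 * 0.95 / len(gwas))
        assert abs(frac - 0.05) <= 3 * sd

    def test_beta_tail_matches_closed_form(self):
        """P(p < a) = a^shape for Beta(shape, 1); at shape 0.3 and a = 0.05
        the expected significant fraction is 0.05^0.3 ~ 0.407."""
        config = tiny_config(seed=4, signal_beta_a=0.3, n_genes=300,
                             esnp_rate=40.0, gwas_coverage=1.0)
        esnp_map = generate_esnp_map(config)
        all_genes = sorted(esnp_map["gene"].unique())
        gwas = generate_gwas_summary(esnp_map, all_genes, config)
        assert len(gwas) >= 10_000
        expected = 0.05**0.3
        frac = (gwas["p"] < 0.05).mean()
        sd = np.sqrt(expected * (1 - expected) / len(gwas))
        assert abs(frac - expected) <= 3 * sd

    def test_empty_true_genes_is_pure_null(self):
        config = tiny_config(seed=5, n_genes=300, esnp_rate=40.0,
                             gwas_coverage=1.0)
        gwas = generate_gwas_summary(generate_esnp_map(config), [], config)
        frac = (gwas["p"] < 0.05).mean()
        sd = np.sqrt(0.05 * 0.95 / len(gwas))
        assert abs(frac - 0.05) <= 3 * sd


class TestLdMap:
    def test_zero_proxy_rate_gives_empty_table_and_identity_expansion(self):
        config = tiny_config(ld_proxy_rate=0.0)
        esnp_map = generate_esnp_map(config)
        ld, proxy_of = generate_ld_map(esnp_map, config)
        assert ld.empty and proxy_of == {}
        snps = set(esnp_map["rsid"][:5])
        assert expand_ld(snps, ld) == snps

    def test_weak_ld_adds_nothing_at_threshold(self):
        config = tiny_config(seed=6, r2_range=(0.0, 0.5), ld_proxy_rate=2.0)
        esnp_map = generate_esnp_map(config)
        ld, _ = generate_ld_map(esnp_map, config)
        snps = set(esnp_map["rsid"])
        assert expand_ld(snps, ld, r2_threshold=0.8) == snps

    def test_expansion_size_matches_poisson_expectation(self):
        """rate 2 with R^2 ~ (0.9, 1): expanded set ~ 3x the original."""
        config = tiny_config(seed=8, r2_range=(0.9, 1.0), ld_proxy_rate=2.0,
                             n_genes=300, esnp_rate=10.0)
        esnp_map = generate_esnp_map(config)
        ld, _ = generate_ld_map(esnp_map, config)
        snps = set(esnp_map["rsid"])
        ratio = len(expand_ld(snps, ld, r2_threshold=0.8)) / len(snps)
        assert ratio == pytest.approx(3.0, rel=0.05)

    def test_proxies_of_true_gene_esnps_inherit_signal(self):
        config = tiny_config(seed=10, signal_beta_a=0.2, ld_proxy_rate=3.0,
                             n_genes=300, esnp_rate=10.0, gwas_coverage=1.0)
        planted = designate_planted_genes(config)
        esnp_map = generate_esnp_map(config)
        ld, proxy_of = generate_ld_map(esnp_map, config)
        gwas = generate_gwas_summary(esnp_map, planted.true_genes, config, proxy_of)
        signal_esnps = set(
            esnp_map.loc[esnp_map["gene"].isin(planted.true_genes), "rsid"])
        signal_proxies = [p for p, s in proxy_of.items() if s in signal_esnps]
        null_proxies = [p for p, s in proxy_of.items() if s not in signal_esnps]
        g = gwas.set_index("rsid")["p"]
        assert g[g.index.intersection(signal_proxies)].median() < 0.1
        assert g[g.index.intersection(null_proxies)].median() > 0.25
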