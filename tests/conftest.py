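"""Shared fixtures: the fixed synthetic study conditions used by the suite.

Two regimes are fixed once for the whole suite:

* ``SIGNAL_PARAMS`` — a planted-signal study: 30 true disease genes with
  elevated co-occurrence in trait-containing modules and Beta(0.3, 1) GWAS
  p-values on their eSNPs, inside a 6,000-gene / 600-module universe with
  lognormal hub structure (a scaled-down analogue of the real data regime).
* ``NULL_PARAMS`` — the same universe with every signal parameter nulled:
  no cis effects, no co-occurrence elevation, uniform GWAS p-values.
"""

import numpy as np
import pandas as pd
import pytest

from snp2net.synthetic_data import SimulationConfig, simulate_all

SIGNAL_PARAMS = dict(
    n_individuals=400,
    n_snps=60,
    n_genes=6000,
    n_modules=600,
    module_size_range=(30, 100),
    n_disease_snps=25,
    n_true_genes=30,
    cis_effect_size=1.0,
    maf_range=(0.1, 0.5),
    signal_beta_a=0.3,
    cooccurrence_prob=0.15,
    hub_sigma=1.2,
    esnp_rate=2.0,
    ld_proxy_rate=1.0,
    r2_range=(0.5, 1.0),
    gwas_coverage=0.9,
)

NULL_PARAMS = dict(
    SIGNAL_PARAMS, cis_effect_size=0.0, signal_beta_a=1.0, cooccurrence_prob=0.0
)

# small universe for fast unit-level checks
TINY_PARAMS = dict(
    n_individuals=300,
    n_snps=20,
    n_genes=300,
    n_modules=60,
    module_size_range=(5, 15),
    n_disease_snps=8,
    n_true_genes=10,
    cis_effect_size=1.5,
    maf_range=(0.15, 0.5),
    signal_beta_a=0.3,
    cooccurrence_prob=0.2,
    hub_sigma=1.0,
)


def signal_config(seed=0, **overrides):
    return SimulationConfig(seed=seed, **{**SIGNAL_PARAMS, **overrides})


def null_config(seed=0, **overrides):
    return SimulationConfig(seed=seed, **{**NULL_PARAMS, **overrides})


def tiny_config(seed=0, **overrides):
    return SimulationConfig(seed=seed, **{**TINY_PARAMS, **overrides})


@pytest.fixture(scope="session")
def tiny_dataset():
    return simulate_all(tiny_config(seed=11))


@pytest.fixture(scope="session")
def signal_dataset():
    return simulate_all(signal_config(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
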