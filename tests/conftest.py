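"""Shared fixtures: small synthetic cohorts generated once per session."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import clonepop as cp


def make_matrix(calls, pos=None, chrom="chr01", ids=None):
    """GenotypeMatrix from a plain call array (tests' little helper)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, S = calls.shape
    if pos is None:
        pos = np.arange(1, S + 1)
    sites = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "T"})
    ids = ids or [f"i{k:02d}" for k in range(n)]
    return cp.GenotypeMatrix(calls, sites, ids)


@pytest.fixture(scope="session")
def clean_cohort(tmp_path_factory):
    """Clonal cohort with no planted blocks or sweep: clonal structure only."""
    cfg = cp.SimConfig(
        n_chromosomes=2, chrom_length=250_000,
        n_isolates_per_epoch={1997: 8, 2007: 8, 2017: 8},
        n_founder_lineages=6, mutation_rate=6e-4, group_mutation_rate=6e-4,
        planted_blocks=[], sweep=None, seed=2)
    return cp.simulate_cohort(cfg, tmp_path_factory.mktemp("clean"))


@pytest.fixture(scope="session")
def full_cohort(tmp_path_factory):
    """Cohort with planted recombinant blocks and a planted sweep."""
    cfg = cp.SimConfig(
        n_chromosomes=3, chrom_length=400_000,
        n_isolates_per_epoch={1997: 10, 2007: 10, 2017: 10},
        n_founder_lineages=8, mutation_rate=8e-4, group_mutation_rate=8e-4,
        seed=1)
    return cp.simulate_cohort(cfg, tmp_path_factory.mktemp("full"))


@pytest.fixture(scope="session")
def neutral_matrix():
    """Neutral-equilibrium haploid cohort (coalescent with recombination)."""
    return cp.simulate_neutral(20, sequence_length=4e5, mutation_rate=1e-7,
                               recombination_rate=1e-7, seed=5)


@pytest.fixture(scope="session")
def admixture_data():
    return cp.simulate_admixture(n_per_pop=20, n_admixed=5, n_sites=2000,
                                 divergence=0.3, seed=3)
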