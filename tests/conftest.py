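"""Shared fixtures: small hand-built genotype matrices and session-scoped
simulation runs reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from founderpop import synthetic_data as sd
from founderpop.variant_store import GenotypeMatrix


def make_matrix(dosages, positions=None, chrom="chr1", samples=None,
                ancestral=None, contig_length=None, **site_cols):
    """Build a GenotypeMatrix from a samples x sites dosage list."""
    g = np.asarray(dosages, dtype=np.int8)
    n_samples, n_sites = g.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    sites = pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(positions, dtype=np.int64),
        "ref": "A", "alt": "G",
        "ancestral": ancestral if ancestral is not None else "unknown",
    })
    for k, v in site_cols.items():
        sites[k] = v
    if samples is None:
        samples = [f"s{i + 1}" for i in range(n_samples)]
    lengths = {chrom: contig_length or int(max(positions) + 100)}
    return GenotypeMatrix(samples, sites, g, contig_lengths=lengths)


@pytest.fixture(scope="session")
def founder_run():
    """One founder-captive simulation shared by ROH/relatedness/diversity tests."""
    return sd.simulate(sd.founder_captive_config(seed=11, n_generations=14))


@pytest.fixture(scope="session")
def hw_cohort():
    """Hardy-Weinberg cohort of independent individuals (null relatedness)."""
    return sd.simulate_hw_cohort(n_individuals=20, n_sites=10_000, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
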