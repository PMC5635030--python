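"""Shared synthetic fixtures: all test data is generated programmatically."""

import numpy as np
import pandas as pd
import pytest

import mwaskit as mk


@pytest.fixture(scope="session")
def small_catalog():
    return mk.generate_catalog(10, (20, 30), seed=11, n_modules=8)


@pytest.fixture(scope="session")
def small_cohort(small_catalog):
    """A 10-genome, 60-sample cohort with 2 enriched / 2 depleted genomes."""
    model = mk.default_community_model(
        small_catalog, n_enriched=2, n_depleted=2, log2_fold_change=2.0, seed=11
    )
    model.sequencing_depth = 50_000
    counts, meta, truth = mk.simulate_cohort(small_catalog, model, 30, 30, seed=12)
    return counts, meta, truth, model


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    counts, meta, truth, model = small_cohort
    rel = mk.relative_abundance(counts)
    filt = mk.filter_low_occurrence(rel, 5)
    return filt, meta, truth


def proportional_gene_matrix(n_genomes, genes_per_genome, n_samples, seed, noise=0.0):
    """Genes perfectly (or nearly) proportional within genomes, independent
    log-normal profiles between genomes; the ideal co-abundance signal."""
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for k in range(n_genomes):
        profile = np.exp(rng.normal(0, 1, size=n_samples))
        weights = np.exp(rng.normal(0, 1, size=genes_per_genome))
        block = np.outer(weights, profile)
        if noise > 0:
            block *= np.exp(rng.normal(0, noise, size=block.shape))
        blocks.append(block)
        labels += [f"genome{k}"] * genes_per_genome
    vals = np.vstack(blocks)
    genes = [f"gene{i:04d}" for i in range(vals.shape[0])]
    m = pd.DataFrame(vals, index=genes, columns=[f"s{j}" for j in range(n_samples)])
    return m / m.sum(axis=0), pd.Series(labels, index=genes)
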