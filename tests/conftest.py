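"""Shared fixtures: small hand-checkable datasets and naive oracles."""

import numpy as np
import pytest

from rigscan import GenotypeDataset
from rigscan.entropy import (
    build_contingency_table,
    relative_information_gain,
)


@pytest.fixture
def toy6():
    """Six samples, two SNPs; contingency counts are hand-tallied in tests."""
    genotypes = np.array(
        [[0, 0], [0, 1], [1, 1], [2, 0], [2, 0], [1, 1]], dtype=np.int8
    )
    phenotype = np.array([1, 1, 0, 1, 0, 1], dtype=np.int8)
    return GenotypeDataset(genotypes=genotypes, phenotype=phenotype)


@pytest.fixture
def xor_dataset():
    """Phenotype equals XOR of SNPs 0 and 1 -> R0 = 1 for that pair only."""
    rng = np.random.default_rng(99)
    n = 80
    g0 = rng.integers(0, 2, n)
    g1 = rng.integers(0, 2, n)
    noise = rng.integers(0, 3, size=(n, 2))
    genotypes = np.column_stack([g0, g1, noise]).astype(np.int8)
    phenotype = (g0 ^ g1).astype(np.int8)
    return GenotypeDataset(genotypes=genotypes, phenotype=phenotype)


def random_dataset(p=8, n=120, seed=0, maf_range=(0.1, 0.5)):
    """Global-null dataset: HWE genotypes independent of a balanced phenotype."""
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(*maf_range, size=p)
    genotypes = rng.binomial(2, mafs[None, :], size=(n, p)).astype(np.int8)
    phenotype = np.zeros(n, dtype=np.int8)
    phenotype[: n // 2] = 1
    phenotype = rng.permutation(phenotype)
    return GenotypeDataset(genotypes=genotypes, phenotype=phenotype)


def naive_scan(dataset, k):
    """Per-table reference scan: one contingency table per combination."""
    import itertools

    out = []
    for combo in itertools.combinations(range(dataset.n_snps), k):
        table = build_contingency_table(dataset, combo)
        out.append(relative_information_gain(table))
    out.sort(key=lambda r: -r.r0)
    return out


def random_table(rng, k, max_count=40):
    """Random 3^k x 2 count table with both classes and some samples present."""
    from rigscan.entropy import ContingencyTable

    while True:
        counts = rng.integers(0, max_count, size=(3**k, 2))
        if counts[:, 0].sum() > 0 and counts[:, 1].sum() > 0:
            return ContingencyTable(tuple(range(k)), counts)
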