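import numpy as np
import pytest

from tigerscan.variants import GenotypeMatrix


def make_gm(
    genotypes,
    positions=None,
    scaffold="scaf1",
    scaffold_length=None,
    populations=None,
    depth=None,
    gq=None,
):
    """Small-matrix builder: genotypes is samples x sites (lists ok)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_sites = g.shape
    if positions is None:
        positions = np.arange(n_sites) * 100
    positions = np.asarray(positions, dtype=np.int64)
    if scaffold_length is None:
        scaffold_length = int(positions[-1]) + 1_000_000 if n_sites else 1_000_000
    if populations is None:
        populations = ["pop1"] * n_samples
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        population_labels=list(populations),
        scaffolds={scaffold: scaffold_length},
        site_scaffolds=np.array([scaffold] * n_sites, dtype=object),
        positions=positions,
        genotypes=g,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
        gq=None if gq is None else np.asarray(gq, dtype=np.int32),
    )


def two_pop_gm(alt_counts_1, alt_counts_2, n_diploids=5):
    """One-site-per-column matrix realizing given per-population alt allele
    counts with ``n_diploids`` diploids per population."""
    alt_counts_1 = np.atleast_1d(alt_counts_1)
    alt_counts_2 = np.atleast_1d(alt_counts_2)
    cols = []
    for a1, a2 in zip(alt_counts_1, alt_counts_2):
        col = []
        for count in (a1, a2):
            gt = [0] * n_diploids
            c = int(count)
            for i in range(n_diploids):
                take = min(2, c)
                gt[i] = take
                c -= take
            col.extend(gt)
        cols.append(col)
    g = np.array(cols, dtype=np.int8).T
    return make_gm(g, populations=["A"] * n_diploids + ["B"] * n_diploids)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
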