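import numpy as np
import pytest

import gfblup as gf


@pytest.fixture(scope="session")
def small_panel():
    """120 inbred accessions x 600 markers with 8 overlapping features."""
    cfg = gf.SimulationConfig(
        n_accessions=120, n_markers=600, n_chromosomes=2, n_genes=80,
        n_features=8, feature_size_range=(3, 12), seed=11,
    )
    geno, genes = gf.simulate_genotypes(cfg)
    feats = gf.simulate_feature_sets(genes, cfg, geno)
    return cfg, geno, genes, feats


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_genotypes(calls, chrom=None, pos=None):
    """Small hand-built GenotypeMatrix helper."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return gf.GenotypeMatrix(
        accession_ids=[f"a{i}" for i in range(n)],
        marker_ids=[f"m{j}" for j in range(m)],
        calls=calls,
        chrom=chrom if chrom is not None else ["chr1"] * m,
        pos=pos if pos is not None else (np.arange(m) + 1) * 100,
    )
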