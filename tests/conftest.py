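import numpy as np
import pandas as pd
import pytest

from radgs.empirical import synth_empirical_dataset
from radgs.genome import SNPCatalogue


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160112)


def make_catalogue(n_loci, chrom_mb=10.0, n_chrom=1, seed=0, freq=None):
    """Random locus map on n_chrom chromosomes with uniform(0.05,0.95)
    initial frequencies unless given."""
    rng = np.random.default_rng(seed)
    per = n_loci // n_chrom
    frames = []
    for c in range(n_chrom):
        k = per if c < n_chrom - 1 else n_loci - per * (n_chrom - 1)
        pos = np.sort(rng.choice(int(chrom_mb * 1e6), k, replace=False))
        frames.append(pd.DataFrame({
            "chrom": f"chr{c+1}", "pos": pos,
            "ref": np.zeros(k, dtype=np.uint8),
            "alt": np.full(k, 2, dtype=np.uint8),
            "freq": rng.uniform(0.05, 0.95, k) if freq is None else freq,
        }))
    return SNPCatalogue(pd.concat(frames, ignore_index=True))


@pytest.fixture(scope="session")
def empirical_data():
    """One shared 5-family synthetic dataset (expensive to build)."""
    return synth_empirical_dataset(seed=7)


@pytest.fixture(scope="session")
def toy_gs_data():
    """Small marker dataset with a sparse genetic architecture."""
    rng = np.random.default_rng(42)
    n, m = 220, 320
    p = rng.uniform(0.1, 0.9, m)
    X = rng.binomial(2, p, size=(n, m)).astype(float)
    g = np.zeros(m)
    nz = rng.choice(m, 25, replace=False)
    g[nz] = rng.normal(0, 0.5, nz.size)
    tbv = X @ g
    y = tbv + rng.normal(0, tbv.std(), n)
    return {"X": X, "y": y, "g": g, "tbv": tbv}
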