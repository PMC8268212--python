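import numpy as np
import pandas as pd
import pytest

from cmgwas import GenotypeMatrix, StrainMatrix


def make_genotypes(dosages, chrom="chr1", spacing=1000, start=1000,
                   chroms=None) -> GenotypeMatrix:
    """GenotypeMatrix from a raw dosage array (animals × variants)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if chroms is None:
        chroms = [chrom] * m
    pos, counters = [], {}
    for c in chroms:
        counters[c] = counters.get(c, 0) + 1
        pos.append(start + (counters[c] - 1) * spacing)
    meta = pd.DataFrame({"chrom": chroms, "pos": pos,
                         "ref": "A", "alt": "G"})
    meta["id"] = [f"{c}:{p}:A:G" for c, p in zip(chroms, pos)]
    return GenotypeMatrix(dosages, meta, [f"an{i:04d}" for i in range(n)])


def make_strains(n, n_strains=3, seed=0) -> StrainMatrix:
    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.full(n_strains, 0.5), size=n)
    return StrainMatrix(Q, [f"strain{i+1}" for i in range(n_strains)],
                        [f"an{i:04d}" for i in range(n)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
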