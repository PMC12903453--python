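import numpy as np
import pandas as pd
import pytest

from rootability.datatypes import GenotypeMatrix


def make_genotypes(dosage, chrom="Chr1", spacing=100, types=None):
    """Small GenotypeMatrix from a raw dosage array (nan = missing)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    sites = pd.DataFrame({
        "chrom": [chrom] * m,
        "pos": np.arange(1, m + 1) * spacing,
        "ref": ["A"] * m,
        "alt": ["C"] * m,
    })
    if types is None:
        types = ["SCC"] * (n // 2) + ["TC"] * (n - n // 2)
    ids = [f"a{i}" for i in range(n)]
    return GenotypeMatrix(ids, types, sites, dosage)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_genotypes(rng):
    """20 accessions x 200 SNPs with some missingness, two groups."""
    freq = rng.uniform(0.1, 0.9, size=200)
    dosage = rng.binomial(2, freq, size=(20, 200)).astype(float)
    dosage[rng.random(dosage.shape) < 0.05] = np.nan
    return make_genotypes(dosage)


@pytest.fixture
def balanced_phenotypes(rng):
    """40 accessions x 2 years x 3 reps with known variance components."""
    from rootability.datatypes import TRAITS

    n, l, r = 40, 2, 3
    g = rng.normal(0, 1, n)
    rows = []
    for i in range(n):
        for j in range(l):
            gy = rng.normal(0, 0.5)
            for k in range(r):
                base = 10 + g[i] + 0.5 * j + gy + rng.normal(0, 0.8)
                row = {"accession": f"a{i:02d}", "type": "SCC", "year": f"Y{j+1}",
                       "rep": k + 1}
                for t in TRAITS:
                    row[t] = max(base, 0.0)
                row["NR"] = 5.0
                row["AL"] = row["TL"] / row["NR"]
                rows.append(row)
    return pd.DataFrame(rows)
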