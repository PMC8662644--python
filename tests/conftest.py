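import numpy as np
import pytest

from colonpop.core import HaplotypeMatrix


def random_matrix(rng, n_sites=60, n_haps=8, missing_rate=0.0,
                  n_chrom=1, chrom_len=1_000_000, cm_per_mb=3.5):
    """A random polarized haplotype matrix (diploid individuals)."""
    assert n_haps % 2 == 0
    per = [n_sites // n_chrom + (1 if i < n_sites % n_chrom else 0)
           for i in range(n_chrom)]
    chrom, pos = [], []
    for i, k in enumerate(per):
        chrom += [f"chr{i + 1}"] * k
        pos.append(np.sort(rng.choice(np.arange(1, chrom_len), size=k,
                                      replace=False)))
    pos_bp = np.concatenate(pos)
    alleles = (rng.random((n_sites, n_haps)) < rng.uniform(
        0.1, 0.9, size=(n_sites, 1))).astype(np.int8)
    if missing_rate > 0:
        alleles[rng.random(alleles.shape) < missing_rate] = -1
    ids = np.repeat([f"ind{i}" for i in range(n_haps // 2)], 2)
    return HaplotypeMatrix(alleles, np.asarray(chrom, dtype=object), pos_bp,
                           pos_bp * cm_per_mb / 1e6, ids)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
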