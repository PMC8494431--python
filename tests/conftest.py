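import numpy as np
import pytest

from autozyg.genotypes import GenotypeMatrix, SampleRecord, Variant


def make_matrix(calls, chroms=None, positions=None, statuses=None,
                spacing_bp=10_000):
    """GenotypeMatrix from a plain nested list / array of calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if chroms is None:
        chroms = [1] * m
    if positions is None:
        positions = [(j + 1) * spacing_bp for j in range(m)]
    if statuses is None:
        statuses = ["case" if i < n // 2 else "control" for i in range(n)]
    variants = [Variant(id=f"v{j}", chrom=int(chroms[j]), pos_bp=int(positions[j]))
                for j in range(m)]
    samples = [SampleRecord(id=f"s{i}", status=statuses[i]) for i in range(n)]
    return GenotypeMatrix(samples, variants, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
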