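import numpy as np
import pytest

from paleokin.io_formats import PseudohaploidMatrix, SnpRecord


def make_snps(n, chrom="1", start=1_000_000, step=1_000_000, ref="A", alt="C"):
    """n SNPs on one chromosome at evenly spaced 1-based positions."""
    return [
        SnpRecord(f"s{i}", chrom, start + i * step, ref, alt) for i in range(n)
    ]


def make_matrix(calls, chrom="1", step=1_000_000, **kw):
    """Pseudohaploid matrix from a {0,2,9} row-per-sample list of lists."""
    calls = np.asarray(calls, dtype=np.int8)
    samples = [f"ind{i}" for i in range(calls.shape[0])]
    return PseudohaploidMatrix(samples, make_snps(calls.shape[1], chrom, step=step), calls, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_923)
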