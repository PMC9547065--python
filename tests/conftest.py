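import numpy as np
import pytest

from chromhub.core import GenomeBuild, GenomicInterval
from chromhub.synth import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle with planted truth (shared across tests)."""
    return simulate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_build():
    return GenomeBuild({"chr1": 1_000_000, "chr2": 600_000})


def random_intervals(rng, build, n, max_len=5000):
    """Uniform random intervals for oracle comparisons."""
    out = []
    chroms = build.chromosomes
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, build[chrom] - length))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


# ---------------------------------------------------------------------------
# Brute-force oracles (deliberately naive; the implementations under test
# must agree with these exactly)
# ---------------------------------------------------------------------------

def brute_join(a, b):
    out = []
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if x.chrom == y.chrom and x.start < y.end and y.start < x.end:
                out.append((i, j))
    return sorted(out)


def brute_closest(query, features):
    best = None
    for idx, f in enumerate(features):
        if f.chrom != query.chrom:
            continue
        if f.start < query.end and query.start < f.end:
            d, signed = 0, 0
        elif f.end <= query.start:
            d = query.start - f.end
            signed = -d
        else:
            d = f.start - query.end
            signed = d
        key = (d, f.start, idx)
        if best is None or key < best[0]:
            best = (key, f, signed)
    return None if best is None else (best[1], best[2])
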