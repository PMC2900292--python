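import numpy as np
import pytest

from ssudiv.distances import DistanceMatrix
from ssudiv.synthdata import SyntheticWorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A 12-taxon synthetic world shared across read-only tests."""
    return generate_world(SyntheticWorldConfig(n_taxa=12, seed=42))


def random_gapped_pair(rng, length=30, gap_p=0.2):
    """Two random equal-length gapped rows guaranteed to share a base column."""
    bases = "ACGT"
    while True:
        rows = []
        for _ in range(2):
            rows.append("".join("-" if rng.random() < gap_p else bases[rng.integers(4)] for _ in range(length)))
        if any(a != "-" and b != "-" for a, b in zip(*rows)):
            return rows[0], rows[1]


def make_dm(ids, dist):
    """DistanceMatrix from a {frozenset({a,b}): d} mapping."""
    cond = []
    for i in range(len(ids)):
        for j in range(i):
            cond.append(dist[frozenset((ids[i], ids[j]))])
    return DistanceMatrix(tuple(ids), np.asarray(cond, dtype=float))
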