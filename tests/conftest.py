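"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own algorithms: the LSAP oracle
enumerates all permutations, the transfer-distance oracle maximizes overlap
over all cluster matchings, and the Mirkin oracle counts discordant item
pairs one by one.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from crpclust import Partition


def lsap_bruteforce(cost: np.ndarray) -> float:
    """Minimum assignment cost by exhaustive permutation search."""
    k = cost.shape[0]
    return min(
        sum(cost[i, p[i]] for i in range(k))
        for p in itertools.permutations(range(k))
    )


def transfer_distance_bruteforce(p1: Partition, p2: Partition) -> int:
    """N minus the best total overlap over all cluster matchings/relabelings."""
    from crpclust import overlap_matrix

    overlap = overlap_matrix(p1, p2)
    k = max(overlap.shape)
    padded = np.zeros((k, k), dtype=np.int64)
    padded[: overlap.shape[0], : overlap.shape[1]] = overlap
    best = max(
        sum(padded[i, p[i]] for i in range(k))
        for p in itertools.permutations(range(k))
    )
    return p1.n - int(best)


def mirkin_similarity_bruteforce(p1: Partition, p2: Partition) -> float:
    """1 - 2(c+d)/N^2 by direct enumeration of all item pairs."""
    n = p1.n
    c = d = 0
    for i, j in itertools.combinations(range(n), 2):
        same1 = p1.labels[i] == p1.labels[j]
        same2 = p2.labels[i] == p2.labels[j]
        c += same1 and not same2
        d += same2 and not same1
    return 1.0 - 2.0 * (c + d) / n**2


def all_set_partitions(n: int):
    """All partitions of n items as restricted-growth label strings."""

    def rec(labels: list[int], next_label: int):
        if len(labels) == n:
            yield Partition(labels)
            return
        for lab in range(next_label + 1):
            yield from rec(labels + [lab], max(next_label, lab + 1))

    yield from rec([0], 1)


def random_partition(rng: np.random.Generator, n: int, max_k: int | None = None) -> Partition:
    max_k = max_k or n
    return Partition(rng.integers(0, rng.integers(1, max_k + 1), size=n))


def crp_expected_clusters(n: int, alpha: float) -> float:
    """Closed-form CRP mean cluster count: sum_i alpha / (alpha + i)."""
    return float(sum(alpha / (alpha + i) for i in range(n)))


def eppf_probability(p: Partition, alpha: float) -> float:
    """Exact CRP exchangeable partition probability:
    alpha^K prod_k (n_k - 1)! / prod_i (alpha + i)."""
    import math

    sizes = p.sizes()
    num = alpha ** len(sizes) * np.prod([math.factorial(int(s) - 1) for s in sizes])
    den = np.prod([alpha + i for i in range(p.n)])
    return float(num / den)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
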