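"""Partitions of a finite item set and label-invariant comparison measures.

A :class:`Partition` assigns each of ``n`` items to an unlabeled cluster.
Cluster ids are arbitrary; every comparison measure here is invariant under
relabeling.  The central distance is the *transfer distance* (TD): the minimum
number of single-item moves needed to turn one partition into the other, up to
relabeling of clusters.  It is computed by reducing to a linear sum assignment
problem (LSAP) over the cluster-overlap matrix.  Two standardized similarities
are derived from pair/move counts:

* Transfer Similarity  ``TS = 1 - TD / (N - 1)``
* Mirkin Similarity    ``MS = 1 - 2 (c + d) / N**2``

where ``c`` counts item pairs co-clustered in the first partition but split in
the second, and ``d`` vice versa.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment


class Partition:
    """An assignment of ``n`` items to ``k`` unlabeled clusters.

    Labels passed in may be any non-negative integers; they are densified to
    ``0 .. k-1`` in order of first appearance, so two partitions that differ
    only by relabeling may still have different stored labels (use
    :meth:`is_equivalent` or :meth:`canonicalize` for label-free comparison).

    Parameters
    ----------
    labels
        Length-``n`` sequence of non-negative integer cluster ids.
    """

    __slots__ = ("labels",)

    def __init__(self, labels: Sequence[int] | np.ndarray):
        arr = np.asarray(labels)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("labels must be a non-empty 1-D sequence")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValueError("cluster ids must be integers")
            arr = arr.astype(np.int64)
        if arr.min() < 0:
            raise ValueError("cluster ids must be non-negative")
        # already-dense ids (0..K-1 all present) are kept verbatim, so
        # canonical numbering survives construction; sparse ids are densified
        # in order of first appearance
        uniq, first, inverse = np.unique(arr, return_index=True, return_inverse=True)
        if uniq[0] == 0 and uniq[-1] == uniq.size - 1:
            self.labels = arr.astype(np.int64)
        else:
            order = np.argsort(np.argsort(first))
            self.labels = order[inverse].astype(np.int64)
        self.labels.setflags(write=False)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_blocks(cls, blocks: Iterable[Iterable[int]]) -> "Partition":
        """Build a partition from explicit member blocks (0-based item ids)."""
        blocks = [list(b) for b in blocks]
        n = sum(len(b) for b in blocks)
        labels = np.empty(n, dtype=np.int64)
        seen = np.zeros(n, dtype=bool)
        for k, block in enumerate(blocks):
            for i in block:
                if i < 0 or i >= n or seen[i]:
                    raise ValueError("blocks must form a partition of 0..n-1")
                labels[i] = k
                seen[i] = True
        return cls(labels)

    # -- basic structure ------------------------------------------------------

    @property
    def n(self) -> int:
        return int(self.labels.size)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1

    def sizes(self) -> np.ndarray:
        """Cluster sizes indexed by cluster id."""
        return np.bincount(self.labels, minlength=self.n_clusters)

    def blocks(self) -> list[np.ndarray]:
        """Member indices per cluster, indexed by cluster id."""
        order = np.argsort(self.labels, kind="stable")
        bounds = np.searchsorted(self.labels[order], np.arange(self.n_clusters + 1))
        return [order[bounds[k]: bounds[k + 1]] for k in range(self.n_clusters)]

    def canonicalize(self) -> "Partition":
        """Renumber clusters by decreasing size, ties by smallest member index."""
        sizes = self.sizes()
        _, first_member = np.unique(self.labels, return_index=True)
        order = sorted(range(self.n_clusters), key=lambda k: (-sizes[k], first_member[k]))
        remap = np.empty(self.n_clusters, dtype=np.int64)
        remap[order] = np.arange(self.n_clusters)
        return Partition(remap[self.labels])

    def is_equivalent(self, other: "Partition") -> bool:
        """True if the two partitions agree up to cluster relabeling."""
        if self.n != other.n:
            return False
        return np.array_equal(self.canonicalize().labels, other.canonicalize().labels)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Partition(n={self.n}, k={self.n_clusters})"

    # -- serialization --------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write a single-column CSV of cluster ids (row order = item order)."""
        with open(path, "w") as fh:
            fh.write("cluster\n")
            fh.writelines(f"{c}\n" for c in self.labels)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Partition":
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        if lines and not lines[0].lstrip("-").isdigit():
            lines = lines[1:]
        return cls([int(x) for x in lines]).canonicalize()

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.labels.tolist())
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Partition":
        if isinstance(source, Path) or (isinstance(source, str) and not source.lstrip().startswith("[")):
            source = Path(source).read_text()
        return cls(json.loads(source)).canonicalize()


# -- LSAP and overlap ---------------------------------------------------------


def solve_lsap(cost: np.ndarray) -> np.ndarray:
    """Minimize the total cost of a one-to-one assignment.

    Parameters
    ----------
    cost
        Square matrix of finite reals; ``cost[i, j]`` is the cost of pairing
        row ``i`` with column ``j``.

    Returns
    -------
    numpy.ndarray
        Permutation ``p`` with ``p[i]`` the column assigned to row ``i``,
        minimizing ``sum(cost[i, p[i]])``.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValueError(f"cost matrix must be square, got shape {cost.shape}")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix must contain only finite values")
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(cost.shape[0], dtype=np.int64)
    perm[rows] = cols
    return perm


def overlap_matrix(p1: Partition, p2: Partition) -> np.ndarray:
    """Cluster contingency table: entry (i, j) = |cluster i of p1 ∩ cluster j of p2|."""
    if p1.n != p2.n:
        raise ValueError(f"partitions cover different item counts: {p1.n} vs {p2.n}")
    k1, k2 = p1.n_clusters, p2.n_clusters
    flat = p1.labels * k2 + p2.labels
    return np.bincount(flat, minlength=k1 * k2).reshape(k1, k2)


def transfer_distance(p1: Partition, p2: Partition) -> int:
    """Minimum number of single-item moves turning ``p1`` into ``p2``.

    Clusters are matched optimally (relabeling is free), so the distance is
    ``N`` minus the maximal total overlap under the best one-to-one matching of
    clusters, obtained by solving an LSAP on the negated, zero-padded overlap
    matrix.
    """
    overlap = overlap_matrix(p1, p2)
    k = max(overlap.shape)
    padded = np.zeros((k, k), dtype=np.int64)
    padded[: overlap.shape[0], : overlap.shape[1]] = overlap
    perm = solve_lsap(-padded.astype(float))
    matched = int(padded[np.arange(k), perm].sum())
    return p1.n - matched


def transfer_similarity(p1: Partition, p2: Partition) -> float:
    """Transfer Similarity ``1 - TD/(N-1)``; requires at least two items."""
    if p1.n != p2.n:
        raise ValueError(f"partitions cover different item counts: {p1.n} vs {p2.n}")
    if p1.n < 2:
        raise ValueError("transfer similarity requires N >= 2")
    return 1.0 - transfer_distance(p1, p2) / (p1.n - 1)


def mirkin_similarity(p1: Partition, p2: Partition) -> float:
    """Mirkin Similarity ``1 - 2(c+d)/N**2`` from discordant pair counts.

    ``c`` = pairs together in ``p1`` but apart in ``p2``; ``d`` = vice versa.
    Computed from the overlap matrix: with row sums ``a``, column sums ``b``
    and entries ``m``, the Mirkin metric is
    ``2(c+d) = sum(a^2) + sum(b^2) - 2 sum(m^2)``.
    """
    m = overlap_matrix(p1, p2)
    a = m.sum(axis=1)
    b = m.sum(axis=0)
    mirkin_metric = float(a @ a) + float(b @ b) - 2.0 * float((m * m).sum())
    return 1.0 - mirkin_metric / p1.n ** 2
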