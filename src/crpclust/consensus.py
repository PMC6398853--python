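"""Median-partition consensus over posterior partition draws and per-cluster
stability.

The consensus ("median") partition minimizes the mean transfer distance to
the set of sampled partitions.  It is found by greedy local search: start from
a candidate, cycle over items, tentatively move each item into every existing
cluster and one new cluster, keep a move only if the mean distance strictly
decreases, and stop after a full cycle without improvement.

Per-cluster stability asks, for each consensus cluster, how often its members
actually stay together across the posterior draws: each draw induces a
sub-partition on the cluster's members, which is compared to the single-block
partition with the Transfer and Mirkin similarities (with ``N`` replaced by
the cluster size).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .partition import (
    Partition,
    mirkin_similarity,
    transfer_distance,
    transfer_similarity,
)


def mean_distance(candidate: Partition, samples: Sequence[Partition]) -> float:
    """Arithmetic mean transfer distance from ``candidate`` to the samples."""
    if len(samples) == 0:
        raise ValueError("need at least one sample partition")
    return float(np.mean([transfer_distance(candidate, s) for s in samples]))


def _dedupe(samples: Sequence[Partition]) -> tuple[list[Partition], np.ndarray]:
    """Group identical (up to relabeling) samples; returns distinct partitions
    and their multiplicities."""
    seen: dict[bytes, int] = {}
    distinct: list[Partition] = []
    weights: list[int] = []
    for p in samples:
        key = p.canonicalize().labels.tobytes()
        if key in seen:
            weights[seen[key]] += 1
        else:
            seen[key] = len(distinct)
            distinct.append(p)
            weights.append(1)
    return distinct, np.asarray(weights, dtype=float)


class _IncrementalMedian:
    """Greedy local-search state: candidate labels plus, per distinct sample,
    the cluster-overlap matrix, updated in O(1) entries per tentative move."""

    def __init__(self, candidate: Partition, distinct: list[Partition], weights: np.ndarray):
        self.n = candidate.n
        self.labels = candidate.canonicalize().labels.copy()
        self.k = int(self.labels.max()) + 1
        self.sizes = np.bincount(self.labels, minlength=self.k).astype(np.int64)
        self.weights = weights
        self.sample_labels = [p.labels for p in distinct]
        self.sample_k = [p.n_clusters for p in distinct]
        # overlaps[s] has an extra all-zero row standing for "a new cluster"
        self.overlaps = []
        for lab, ks in zip(self.sample_labels, self.sample_k):
            o = np.zeros((self.k + 1, ks), dtype=np.int64)
            np.add.at(o, (self.labels, lab), 1)
            self.overlaps.append(o)

    @staticmethod
    def _max_matching(overlap: np.ndarray) -> int:
        rows, cols = linear_sum_assignment(overlap, maximize=True)
        return int(overlap[rows, cols].sum())

    def weighted_mean_td(self) -> float:
        total = 0.0
        for o, w in zip(self.overlaps, self.weights):
            total += w * (self.n - self._max_matching(o))
        return total / self.weights.sum()

    def try_move(self, i: int, target: int) -> float:
        """Weighted mean TD if item ``i`` moved to cluster ``target``
        (``target == k`` means a new cluster); state is left unchanged."""
        src = self.labels[i]
        total = 0.0
        for o, lab, w in zip(self.overlaps, self.sample_labels, self.weights):
            j = lab[i]
            o[src, j] -= 1
            o[target, j] += 1
            total += w * (self.n - self._max_matching(o))
            o[src, j] += 1
            o[target, j] -= 1
        return total / self.weights.sum()

    def apply_move(self, i: int, target: int) -> None:
        src = self.labels[i]
        new_cluster = target == self.k
        for o, lab in zip(self.overlaps, self.sample_labels):
            j = lab[i]
            o[src, j] -= 1
            o[target, j] += 1
        if new_cluster:
            # the spare zero row became a real cluster; append a fresh spare
            self.overlaps = [
                np.vstack([o, np.zeros((1, o.shape[1]), dtype=np.int64)])
                for o in self.overlaps
            ]
            self.sizes = np.append(self.sizes, 1)
            self.k += 1
        else:
            self.sizes[target] += 1
        self.labels[i] = target
        self.sizes[src] -= 1
        if self.sizes[src] == 0:
            self._drop_cluster(src)

    def _drop_cluster(self, src: int) -> None:
        self.sizes = np.delete(self.sizes, src)
        self.labels[self.labels > src] -= 1
        self.k -= 1
        self.overlaps = [np.delete(o, src, axis=0) for o in self.overlaps]

    def partition(self) -> Partition:
        return Partition(self.labels).canonicalize()


def median_partition(
    samples: Sequence[Partition],
    seed: int | None = None,
    start: str = "best",
) -> Partition:
    """Greedy median partition of a set of sampled partitions.

    The initial candidate is the sample with the smallest mean transfer
    distance to all samples (``start="best"``, deterministic) or a uniformly
    chosen sample (``start="random"``, requires ``seed``).  Moves are accepted
    only on a strict decrease of the mean distance, so the search cannot
    cycle; the result's mean distance never exceeds the initial candidate's.
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample partition")
    n = samples[0].n
    if any(p.n != n for p in samples):
        raise ValueError("all sample partitions must cover the same items")
    distinct, weights = _dedupe(samples)
    if start == "random":
        rng = np.random.default_rng(seed)
        candidate = samples[int(rng.integers(len(samples)))]
    elif start == "best":
        wd = [float(np.dot(weights, [transfer_distance(c, s) for s in distinct]))
              for c in distinct]
        candidate = distinct[int(np.argmin(wd))]
    else:
        raise ValueError("start must be 'best' or 'random'")

    search = _IncrementalMedian(candidate, distinct, weights)
    best = search.weighted_mean_td()
    improved = True
    while improved:
        improved = False
        for i in range(n):
            current_cluster = search.labels[i]
            singleton = search.sizes[current_cluster] == 1
            targets = [t for t in range(search.k) if t != current_cluster]
            if not singleton:
                targets.append(search.k)  # a brand-new cluster
            for target in targets:
                score = search.try_move(i, target)
                if score < best - 1e-12:
                    search.apply_move(i, target)
                    best = score
                    improved = True
                    break
    return search.partition()


@dataclass
class ClusterStability:
    cluster: int
    size: int
    mean_transfer_similarity: float | None
    mean_mirkin_similarity: float


@dataclass
class StabilityReport:
    """Per-consensus-cluster mean similarity of the induced sub-partitions
    across all sampled partitions.  Singleton clusters have no defined
    Transfer Similarity (its denominator is ``|C| - 1``)."""

    clusters: list[ClusterStability]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps([asdict(c) for c in self.clusters], indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["cluster", "size", "mean_transfer_similarity", "mean_mirkin_similarity"])
            for c in self.clusters:
                ts = "" if c.mean_transfer_similarity is None else f"{c.mean_transfer_similarity:.6f}"
                writer.writerow([c.cluster, c.size, ts, f"{c.mean_mirkin_similarity:.6f}"])


def cluster_stability(median: Partition, samples: Sequence[Partition]) -> StabilityReport:
    """Stability of each median-partition cluster across the sampled draws."""
    if len(samples) == 0:
        raise ValueError("need at least one sample partition")
    median = median.canonicalize()
    rows: list[ClusterStability] = []
    for k, members in enumerate(median.blocks()):
        size = members.size
        block = Partition(np.zeros(size, dtype=np.int64))
        ts_vals: list[float] = []
        ms_vals: list[float] = []
        for s in samples:
            induced = Partition(s.labels[members])
            if size >= 2:
                ts_vals.append(transfer_similarity(block, induced))
            ms_vals.append(mirkin_similarity(block, induced))
        rows.append(
            ClusterStability(
                cluster=k,
                size=int(size),
                mean_transfer_similarity=float(np.mean(ts_vals)) if size >= 2 else None,
                mean_mirkin_similarity=float(np.mean(ms_vals)),
            )
        )
    return StabilityReport(rows)


def run_disagreement(median_a: Partition, median_b: Partition) -> tuple[int, float]:
    """Minimal number (and fraction of N) of items whose cluster assignment
    must change to reconcile two consensus partitions."""
    td = transfer_distance(median_a, median_b)
    return td, td / median_a.n
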