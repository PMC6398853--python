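"""End-to-end analysis: sample -> consensus -> stability -> cluster profiles.

``run_analysis`` reproduces the study workflow on any
:class:`~crpclust.data.CategoricalDataset`: run independent replicate chains
of the collapsed Gibbs sampler, compare the per-chain consensus partitions
(run disagreement), build the pooled-sample median partition, quantify
per-cluster stability, and profile every consensus cluster by its per-item
response frequencies and, when present, its outcome (party-identification)
frequencies with enrichment ratios against the whole sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .consensus import (
    StabilityReport,
    cluster_stability,
    median_partition,
    run_disagreement,
)
from .data import CategoricalDataset
from .partition import Partition
from .sampler import SampleChain, SamplerConfig, run_chain


@dataclass
class ClusterProfile:
    """Descriptive summary of one cluster: per-item response-option
    proportions and, if available, outcome-category proportions."""

    cluster: int
    size: int
    item_frequencies: dict[str, list[float]]
    outcome_frequencies: dict[str, float] | None = None


def profile_clusters(data: CategoricalDataset, partition: Partition) -> list[ClusterProfile]:
    """Per-cluster response and outcome frequency tables, in cluster-id order."""
    if partition.n != data.n:
        raise ValueError("partition does not cover the dataset rows")
    outcome_categories = sorted(set(data.outcome)) if data.outcome is not None else None
    outcome_arr = np.asarray(data.outcome) if data.outcome is not None else None
    profiles = []
    for k, members in enumerate(partition.blocks()):
        size = members.size
        item_freqs: dict[str, list[float]] = {}
        for d, label in enumerate(data.item_labels):
            counts = np.bincount(
                data.responses[members, d], minlength=int(data.category_counts[d])
            )
            item_freqs[label] = (counts / size).tolist()
        outcome_freqs = None
        if outcome_arr is not None:
            sub = outcome_arr[members]
            outcome_freqs = {
                cat: float(np.count_nonzero(sub == cat)) / size
                for cat in outcome_categories
            }
        profiles.append(ClusterProfile(k, int(size), item_freqs, outcome_freqs))
    return profiles


def whole_sample_profile(data: CategoricalDataset) -> ClusterProfile:
    """Marginal frequencies of the full sample (single-block partition)."""
    return profile_clusters(data, Partition(np.zeros(data.n, dtype=np.int64)))[0]


def outcome_enrichment(profile: ClusterProfile, overall: ClusterProfile) -> dict[str, float | None]:
    """Cluster-vs-sample outcome ratio per category (1 = no enrichment).

    Categories absent from the whole sample have no defined ratio (``None``).
    """
    if profile.outcome_frequencies is None or overall.outcome_frequencies is None:
        raise ValueError("both profiles need outcome frequencies")
    if set(profile.outcome_frequencies) != set(overall.outcome_frequencies):
        raise ValueError("outcome categories differ between profiles")
    ratios: dict[str, float | None] = {}
    for cat, p in profile.outcome_frequencies.items():
        q = overall.outcome_frequencies[cat]
        ratios[cat] = None if q == 0 else p / q
    return ratios


@dataclass
class AnalysisReport:
    """Everything the workflow produces, ready for JSON serialization."""

    median: Partition
    cluster_sizes: list[int]
    stability: StabilityReport
    profiles: list[ClusterProfile]
    overall_profile: ClusterProfile
    enrichment: list[dict[str, float | None]] | None
    chain_medians: list[Partition]
    disagreement_count: int | None
    disagreement_fraction: float | None
    config: SamplerConfig
    chain: SampleChain = field(repr=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config": asdict(self.config),
            "median_partition": self.median.labels.tolist(),
            "cluster_sizes": self.cluster_sizes,
            "n_clusters": len(self.cluster_sizes),
            "disagreement_count": self.disagreement_count,
            "disagreement_fraction": self.disagreement_fraction,
            "stability": [asdict(c) for c in self.stability.clusters],
            "profiles": [asdict(p) for p in self.profiles],
            "overall_profile": asdict(self.overall_profile),
            "enrichment": self.enrichment,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_analysis(
    data: CategoricalDataset,
    cfg: SamplerConfig,
) -> AnalysisReport:
    """Full workflow on one dataset; deterministic given ``cfg.seed``."""
    chain = run_chain(data, cfg)
    chain_medians = [
        median_partition(chain.by_chain(c)) for c in range(cfg.n_chains)
    ]
    if cfg.n_chains >= 2:
        count, fraction = run_disagreement(chain_medians[0], chain_medians[1])
    else:
        count = fraction = None
    median = (
        median_partition(chain.partitions)
        if cfg.n_chains >= 2
        else chain_medians[0]
    )
    stability = cluster_stability(median, chain.partitions)
    profiles = profile_clusters(data, median)
    overall = whole_sample_profile(data)
    enrichment = None
    if data.outcome is not None:
        enrichment = [outcome_enrichment(p, overall) for p in profiles]
    return AnalysisReport(
        median=median,
        cluster_sizes=[int(s) for s in median.sizes()],
        stability=stability,
        profiles=profiles,
        overall_profile=overall,
        enrichment=enrichment,
        chain_medians=chain_medians,
        disagreement_count=count,
        disagreement_fraction=fraction,
        config=cfg,
        chain=chain,
    )
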