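"""Synthetic survey data with known latent cluster structure.

The generator emulates the shape of a German household-panel concern block:
13 categorical dimensions — eleven 3-point concern items, one employment item
with a fourth "not applicable" level for respondents without employment, and
one binary "other concerns" indicator — paired with a party-identification
outcome dominated by a large "none" category.

Latent structure: cluster labels are drawn either from a Chinese Restaurant
Process (rich-gets-richer size decay) or from explicit weights; each cluster
owns, per dimension, a response-probability vector drawn from a symmetric
Dirichlet(gamma) — small ``gamma`` pushes the profiles toward corners and
therefore separates the clusters.  Items are conditionally independent given
the cluster, exactly the mixture model's own likelihood assumption.  The
outcome is drawn from a cluster-specific distribution that keeps "none"
around one half everywhere while tilting selected clusters toward one party.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import CategoricalDataset
from .partition import Partition, transfer_similarity

#: Default item block: 11 three-level concern items, employment safety with an
#: extra not-applicable level, and a binary other-concerns indicator.
DEFAULT_ITEM_SPEC: list[tuple[str, int]] = [
    ("economy_general", 3),
    ("own_finances", 3),
    ("financial_markets", 3),
    ("own_health", 3),
    ("environment", 3),
    ("climate_change", 3),
    ("peacekeeping", 3),
    ("terrorism", 3),
    ("crime", 3),
    ("employment_safety", 4),
    ("immigration", 3),
    ("xenophobia", 3),
    ("other_concerns", 2),
]

#: Default outcome categories: no identification plus seven party options.
DEFAULT_OUTCOME_CATEGORIES: list[str] = [
    "none", "party_a", "party_b", "party_c", "party_d",
    "party_e", "party_f", "other",
]

#: Whole-population outcome shape: a slight majority reports no leaning and
#: two larger parties dominate the remainder.
_BASE_OUTCOME = np.array([0.50, 0.18, 0.14, 0.05, 0.04, 0.03, 0.02, 0.04])


@dataclass
class GeneratorConfig:
    """Study-shaped generator settings.

    n : number of respondents (default: the emulated panel's sample size).
    scheme : "crp" (size-decaying clusters via a CRP with ``alpha_gen``) or
        "explicit" (fixed ``weights`` over ``n_clusters`` clusters).
    alpha_gen : CRP concentration for the "crp" scheme.
    weights : cluster probabilities for the "explicit" scheme.
    item_spec : (label, category count) per dimension.
    separation : symmetric Dirichlet concentration gamma for the per-cluster
        response profiles; smaller = better separated clusters.
    outcome_categories / outcome_tilt : outcome labels and how strongly a
        cluster's favored party is over-weighted (0 = identical everywhere).
    seed : reproducibility seed.
    """

    n: int = 8170
    scheme: str = "crp"
    alpha_gen: float = 1.0
    n_clusters: int | None = None
    weights: Sequence[float] | None = None
    item_spec: list[tuple[str, int]] = field(default_factory=lambda: list(DEFAULT_ITEM_SPEC))
    separation: float = 0.1
    outcome_categories: list[str] = field(default_factory=lambda: list(DEFAULT_OUTCOME_CATEGORIES))
    outcome_tilt: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.scheme not in {"crp", "explicit"}:
            raise ValueError("scheme must be 'crp' or 'explicit'")
        if self.scheme == "crp" and self.alpha_gen <= 0:
            raise ValueError("alpha_gen must be > 0 for the crp scheme")
        if self.scheme == "explicit":
            if self.weights is None:
                raise ValueError("explicit scheme requires weights")
            w = np.asarray(self.weights, dtype=float)
            if w.ndim != 1 or w.size < 1 or np.any(w <= 0):
                raise ValueError("weights must be positive")
            if self.n_clusters is not None and self.n_clusters != w.size:
                raise ValueError("n_clusters disagrees with len(weights)")
        if self.separation <= 0:
            raise ValueError("separation (gamma) must be > 0")
        if any(v < 2 for _, v in self.item_spec):
            raise ValueError("every item needs at least 2 categories")
        if not 0 <= self.outcome_tilt < 1:
            raise ValueError("outcome_tilt must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic dataset."""

    partition: Partition
    profiles: list[list[np.ndarray]]  # [cluster][dimension] -> prob vector
    outcome_distributions: np.ndarray  # (K, n_outcomes)


def _crp_labels(n: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    labels = np.zeros(n, dtype=np.int64)
    sizes: list[int] = []
    for i in range(n):
        probs = np.array(sizes + [alpha], dtype=float)
        k = int(rng.choice(probs.size, p=probs / probs.sum()))
        if k == len(sizes):
            sizes.append(1)
        else:
            sizes[k] += 1
        labels[i] = k
    return labels


def _default_outcome_distributions(
    k: int, categories: list[str], tilt: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-cluster outcome distributions: the population shape, with each
    cluster tilted toward one (seeded) party drawn from the base shares."""
    base = _BASE_OUTCOME[: len(categories)].copy()
    base /= base.sum()
    out = np.tile(base, (k, 1))
    party_mass = 1.0 - base[0]
    party_shares = base[1:] / party_mass
    for c in range(k):
        fav = int(rng.choice(np.arange(1, len(categories)), p=party_shares))
        tilted = (1.0 - tilt) * party_shares.copy()
        tilted[fav - 1] += tilt
        out[c, 1:] = party_mass * tilted
    return out


def generate(cfg: GeneratorConfig) -> tuple[CategoricalDataset, SyntheticTruth]:
    """Draw a dataset and its ground truth from the generator model."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.scheme == "crp":
        labels = _crp_labels(cfg.n, cfg.alpha_gen, rng)
    else:
        w = np.asarray(cfg.weights, dtype=float)
        labels = rng.choice(w.size, size=cfg.n, p=w / w.sum())
    truth_partition = Partition(labels)
    k = truth_partition.n_clusters
    labels = truth_partition.labels

    category_counts = np.array([v for _, v in cfg.item_spec], dtype=np.int64)
    profiles: list[np.ndarray] = []
    for _ in range(k):
        profiles.append(
            [rng.dirichlet(np.full(v, cfg.separation)) for v in category_counts]
        )
    responses = np.empty((cfg.n, len(cfg.item_spec)), dtype=np.int64)
    for c in range(k):
        members = np.flatnonzero(labels == c)
        for d, v in enumerate(category_counts):
            responses[members, d] = rng.choice(v, size=members.size, p=profiles[c][d])

    outcome_dists = _default_outcome_distributions(
        k, cfg.outcome_categories, cfg.outcome_tilt, rng
    )
    outcome_codes = np.empty(cfg.n, dtype=np.int64)
    for c in range(k):
        members = np.flatnonzero(labels == c)
        outcome_codes[members] = rng.choice(
            len(cfg.outcome_categories), size=members.size, p=outcome_dists[c]
        )
    outcome = [cfg.outcome_categories[i] for i in outcome_codes]

    dataset = CategoricalDataset(
        responses=responses,
        category_counts=category_counts,
        item_labels=[lbl for lbl, _ in cfg.item_spec],
        outcome=outcome,
        outcome_name="party_identification",
    )
    truth = SyntheticTruth(
        partition=truth_partition,
        profiles=profiles,
        outcome_distributions=outcome_dists,
    )
    return dataset, truth


def truth_recovery_score(truth: SyntheticTruth, estimate: Partition) -> float:
    """Transfer Similarity between the generating partition and an estimate."""
    if truth.partition.n != estimate.n:
        raise ValueError("estimate does not cover the generated items")
    return transfer_similarity(truth.partition, estimate)
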